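"""Bag-of-words groups, topic model, and feature assembly."""

import numpy as np
import pytest
import scipy.sparse as sp

from picoscreen.features import (
    BASELINE_GROUPS,
    GROUP_ORDER,
    TopicModelConfig,
    assemble_features,
    build_bow,
    build_feature_matrix,
    build_pico_bows,
    build_vocab,
    fit_topic_model,
    infer_topics,
    lda_token_filter,
    load_feature_matrix,
    save_feature_matrix,
)
from picoscreen.pico_tagger import SpanAnnotation
from picoscreen.textprep import Document, preprocess_document


def _doc(doc_id, title, abstract="", label="unlabelled"):
    return preprocess_document(Document(doc_id, title, abstract, label))


class TestVocabulary:
    def test_union_over_documents(self):
        docs = [_doc("a", "Steroid therapy"), _doc("b", "Steroid withdrawal")]
        vocab = build_vocab(docs, "title")
        assert set(vocab.index) == {"steroid", "therapy", "withdrawal"}

    def test_deterministic_lexicographic_order(self):
        docs = [_doc("a", "Zinc versus placebo treatment")]
        v1 = build_vocab(docs, "titleabs")
        v2 = build_vocab(docs, "titleabs")
        assert v1.lemmata == sorted(v1.index) and v1.index == v2.index

    def test_stopword_only_content_excluded(self):
        docs = [_doc("a", "The and of", "Within about")]
        with pytest.raises(ValueError, match="empty vocabulary"):
            build_vocab(docs, "titleabs")

    def test_labels_never_consulted(self):
        inc = [_doc("a", "Steroid therapy", label="included")]
        exc = [_doc("a", "Steroid therapy", label="excluded")]
        assert build_vocab(inc, "title").index == build_vocab(exc, "title").index


class TestBuildBow:
    def test_four_lemmata_give_half_entries(self):
        docs = [_doc("a", "Alpha beta gamma delta")]
        vocab = build_vocab(docs, "title")
        row = build_bow({"alpha", "beta", "gamma", "delta"}, vocab)
        assert row.nnz == 4
        np.testing.assert_allclose(row.data, 0.5)

    def test_empty_bag_stays_zero(self):
        docs = [_doc("a", "Alpha beta")]
        vocab = build_vocab(docs, "title")
        row = build_bow(set(), vocab)
        assert row.nnz == 0

    def test_single_lemma_is_unit_basis(self):
        docs = [_doc("a", "Alpha beta")]
        vocab = build_vocab(docs, "title")
        row = build_bow({"alpha"}, vocab)
        assert row.nnz == 1 and row.data[0] == 1.0

    def test_out_of_vocabulary_lemmata_ignored(self):
        docs = [_doc("a", "Alpha beta")]
        vocab = build_vocab(docs, "title")
        row = build_bow({"alpha", "zz-not-there"}, vocab)
        assert row.nnz == 1 and row.data[0] == 1.0


class TestPicoBows:
    def test_no_spans_three_empty_sets(self):
        bows = build_pico_bows(_doc("a", "Alpha beta"))
        assert bows == {"P": set(), "I": set(), "O": set()}

    def test_outcome_span_lemmata(self):
        doc = _doc("a", "Steroids reduce acute rejection")
        ref = doc.sentences[0].ref
        doc.spans = [SpanAnnotation("O", ref, 2, 4)]
        assert build_pico_bows(doc)["O"] == {"acute", "rejection"}

    def test_nested_spans_contribute_to_both_bags(self):
        doc = _doc("a", "Paediatric kidney transplant recipients")
        ref = doc.sentences[0].ref
        doc.spans = [SpanAnnotation("P", ref, 0, 4), SpanAnnotation("I", ref, 1, 3)]
        bows = build_pico_bows(doc)
        assert {"kidney", "transplant"} <= bows["I"]
        assert {"kidney", "transplant", "paediatric", "recipient"} <= bows["P"]

    def test_fine_grained_mapped_to_parent(self):
        doc = _doc("a", "Severe chronic pain")
        ref = doc.sentences[0].ref
        doc.spans = [SpanAnnotation("O.Pain", ref, 1, 3)]
        assert build_pico_bows(doc)["O"] == {"chronic", "pain"}


class TestLdaFilter:
    @pytest.mark.parametrize(
        "token,kept",
        [
            ("pain", True),
            ("beta-blocker", True),
            ("'quoted", True),
            ("trailing-", False),
            ("p53", False),
            ("123", False),
            ("the", False),
        ],
    )
    def test_filter_rules(self, token, kept):
        out = lda_token_filter(token, {"the"})
        assert (out is not None) == kept


def _topic_corpus(n_docs=120, seed=0):
    """Two disjoint sub-vocabularies; half the documents draw from each."""
    rng = np.random.default_rng(seed)
    vocab_a = [f"alpha{c}" for c in "bcdfghjklm"]
    vocab_b = [f"omega{c}" for c in "bcdfghjklm"]
    docs = []
    for d in range(n_docs):
        vocab = vocab_a if d % 2 == 0 else vocab_b
        words = [vocab[i] for i in rng.integers(0, len(vocab), size=20)]
        docs.append(_doc(f"d{d}", "Topic corpus entry", " ".join(words).capitalize() + "."))
    return docs


class TestTopicModel:
    def test_single_topic_is_forced(self):
        docs = _topic_corpus(10)
        model = fit_topic_model(docs, TopicModelConfig(k=1, n_iterations=10, seed=0))
        theta = infer_topics(docs[0], model)
        assert theta.shape == (1,) and theta[0] == pytest.approx(1.0)

    def test_planted_two_topic_structure_recovered(self):
        docs = _topic_corpus(120, seed=1)
        model = fit_topic_model(docs, TopicModelConfig(k=2, n_iterations=200, seed=1))
        dominant = model.doc_topic.argmax(axis=1)
        even, odd = dominant[::2], dominant[1::2]
        purity = max(
            (np.mean(even == 0) + np.mean(odd == 1)) / 2,
            (np.mean(even == 1) + np.mean(odd == 0)) / 2,
        )
        assert purity >= 0.9

    def test_same_seed_identical_counts(self):
        docs = _topic_corpus(30)
        cfg = TopicModelConfig(k=3, n_iterations=30, seed=5)
        m1 = fit_topic_model(docs, cfg)
        m2 = fit_topic_model(docs, cfg)
        np.testing.assert_array_equal(m1.topic_word, m2.topic_word)
        np.testing.assert_array_equal(m1.doc_topic, m2.doc_topic)

    def test_inferred_topics_unit_norm_or_zero(self):
        docs = _topic_corpus(30)
        model = fit_topic_model(docs[:20], TopicModelConfig(k=3, n_iterations=30, seed=2))
        for doc in docs[20:]:
            theta = infer_topics(doc, model)
            assert np.linalg.norm(theta) == pytest.approx(1.0, abs=1e-9)
        empty = _doc("e", "The of and")
        assert np.linalg.norm(infer_topics(empty, model)) == 0.0

    def test_unseen_dominant_topic_matches_planted_vocabulary(self):
        docs = _topic_corpus(120, seed=1)
        model = fit_topic_model(docs, TopicModelConfig(k=2, n_iterations=200, seed=1))
        probe = _doc("probe", "Probe entry", "Alphab alphac alphad alphaf alphag.")
        theta = infer_topics(probe, model)
        train_dominant = model.doc_topic.argmax(axis=1)[::2]  # vocab-a documents
        expected = np.bincount(train_dominant, minlength=2).argmax()
        assert theta.argmax() == expected


class TestAssembly:
    def _vocabs(self, docs):
        return build_vocab(docs, "title"), build_vocab(docs, "titleabs")

    def test_group_counts_by_mode(self):
        docs = [_doc("a", "Alpha beta", "Gamma delta.")]
        vt, vta = self._vocabs(docs)
        theta = np.array([1.0])
        baseline = assemble_features(docs[0], theta, vt, vta, "baseline")
        pico = assemble_features(docs[0], theta, vt, vta, "pico")
        assert set(baseline.groups) == set(BASELINE_GROUPS)
        assert set(pico.groups) == set(GROUP_ORDER)

    def test_unknown_mode_rejected(self):
        docs = [_doc("a", "Alpha beta")]
        vt, vta = self._vocabs(docs)
        with pytest.raises(ValueError, match="mode"):
            assemble_features(docs[0], np.ones(1), vt, vta, "bert")

    def test_pico_mode_without_spans_extends_baseline_with_zeros(self):
        docs = [_doc("a", "Alpha beta", "Gamma delta.")]
        vt, vta = self._vocabs(docs)
        theta = np.array([1.0])
        base = assemble_features(docs[0], theta, vt, vta, "baseline").concat()
        pico = assemble_features(docs[0], theta, vt, vta, "pico").concat()
        assert pico.shape[1] == base.shape[1] + 3 * len(vta)
        for cat in ("P", "I", "O"):
            grp = assemble_features(docs[0], theta, vt, vta, "pico").groups[f"bow_{cat}"]
            assert grp.nnz == 0

    def test_feature_dimension_arithmetic(self, relevance_study):
        # pico mode adds exactly three copies of the titleabs vocabulary width
        Xb, Xp = relevance_study["X_baseline"], relevance_study["X_pico"]
        tagged = relevance_study["tagged"]
        vta = build_vocab(tagged, "titleabs")
        assert Xp.shape[1] == Xb.shape[1] + 3 * len(vta)

    def test_groups_unit_norm_and_pico_support_subset(self, relevance_study):
        tagged = relevance_study["tagged"]
        vt = build_vocab(tagged, "title")
        vta = build_vocab(tagged, "titleabs")
        doc = next(t for t in tagged if t.spans)
        fv = assemble_features(doc, np.ones(3) / np.sqrt(3), vt, vta, "pico")
        for name, grp in fv.groups.items():
            if grp.nnz:
                assert sp.linalg.norm(grp) == pytest.approx(1.0, abs=1e-9)
        bow_support = set(fv.groups["bow_titleabs"].indices)
        for cat in ("P", "I", "O"):
            assert set(fv.groups[f"bow_{cat}"].indices) <= bow_support


class TestPersistence:
    def test_mtx_round_trip(self, tmp_path):
        docs = [_doc("a", "Alpha beta", "Gamma delta."), _doc("b", "Beta epsilon")]
        X, meta = build_feature_matrix(
            docs, "baseline", TopicModelConfig(k=2, n_iterations=20, seed=0)
        )
        save_feature_matrix(X, meta, tmp_path / "features")
        X2, meta2 = load_feature_matrix(tmp_path / "features")
        assert (X != X2).nnz == 0
        assert meta2["doc_ids"] == meta["doc_ids"]
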