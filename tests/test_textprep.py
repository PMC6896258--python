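"""Preprocessing and file-format tests."""

import pytest

from picoscreen.textprep import (
    Collection,
    CollectionError,
    Document,
    filter_bow_lemmata,
    lemmatize,
    load_stopwords,
    normalise_for_tagger,
    preprocess_document,
    read_annotated_corpus,
    read_collection,
    split_sentences,
    tokenize,
    write_annotated_corpus,
    write_collection,
)


class TestSentenceSplitting:
    def test_empty_text_yields_no_sentences(self):
        assert split_sentences("") == []
        assert split_sentences("   ") == []

    def test_single_sentence_covers_text(self):
        (s,) = split_sentences("One sentence.")
        assert (s.char_start, s.char_end) == (0, 13)

    def test_terminator_before_capital_splits(self):
        spans = [(s.char_start, s.char_end) for s in split_sentences("A was tested. B was not.")]
        assert spans == [(0, 13), (14, 24)]

    def test_offsets_cover_non_whitespace(self):
        text = "Alpha beta.  Gamma delta!  Epsilon?"
        covered = set()
        for s in split_sentences(text):
            covered |= set(range(s.char_start, s.char_end))
        uncovered = [i for i, c in enumerate(text) if not c.isspace() and i not in covered]
        assert uncovered == []


class TestTokenisation:
    def test_word_lemmata(self):
        toks = tokenize("Steroids reduced")
        assert [t.surface for t in toks] == ["Steroids", "reduced"]
        assert [t.lemma for t in toks] == ["steroid", "reduce"]

    def test_punctuation_and_decimals(self):
        assert [t.surface for t in tokenize("p<0.05")] == ["p", "<", "0.05"]

    def test_single_letter(self):
        (tok,) = tokenize("A")
        assert tok.lemma == "a"

    def test_offsets_match_surfaces(self):
        text = "Randomised, double-blind trial (n=120)."
        for t in tokenize(text):
            assert text[t.char_start : t.char_end] == t.surface

    @pytest.mark.parametrize(
        "surface,lemma",
        [
            ("studies", "study"),
            ("classes", "class"),
            ("outcomes", "outcome"),
            ("increased", "increase"),
            ("planned", "plan"),
            ("testing", "test"),
            ("agreed", "agree"),
            ("migraine-specific", "migraine-specific"),
        ],
    )
    def test_suffix_rules(self, surface, lemma):
        assert lemmatize(surface) == lemma


class TestTaggerNormalisation:
    def test_digits_and_case(self):
        assert normalise_for_tagger("Mg2+") == "mg0+"
        assert normalise_for_tagger("ABC") == "abc"
        assert normalise_for_tagger("2019") == "0000"


class TestBowFilter:
    def test_rules(self):
        assert filter_bow_lemmata(["the", "pain", "p", ";;"], {"the"}) == {"pain"}
        assert filter_bow_lemmata([], set()) == set()
        assert filter_bow_lemmata(["a1", "-x", "--"], set()) == {"a1", "-x"}

    def test_default_stopwords_loaded(self):
        sw = load_stopwords()
        assert "the" in sw and "pain" not in sw


def _collection():
    return Collection(
        "demo",
        [
            Document("d1", "Steroids in transplant recipients.", "Acute rejection was reduced.", "included"),
            Document("d2", "Placebo comparison.", "", "excluded"),
            Document("d3", "Unlabelled title.", "Some abstract."),
        ],
    )


class TestCollectionIO:
    @pytest.mark.parametrize("fmt", ["csv", "tsv", "ris"])
    def test_round_trip(self, tmp_path, fmt):
        col = _collection()
        path = tmp_path / f"col.{fmt}"
        write_collection(col, path)
        back = read_collection(path)
        assert [(d.id, d.title, d.abstract, d.label) for d in back] == [
            (d.id, d.title, d.abstract, d.label) for d in col
        ]

    def test_label_aliases(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,title,abstract,label\na,T one,,1\nb,T two,,0\nc,T three,,\n")
        col = read_collection(path)
        assert col.labels() == ["included", "excluded", "unlabelled"]

    def test_duplicate_id_is_an_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,title,abstract,label\na,T,,1\na,T2,,0\n")
        with pytest.raises(CollectionError, match="'a'"):
            read_collection(path)

    def test_missing_title_is_an_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,title,abstract,label\na,,,1\n")
        with pytest.raises(CollectionError, match="title"):
            read_collection(path)


class TestAnnotatedCorpusIO:
    def _tagged(self):
        from picoscreen.pico_tagger import SpanAnnotation

        tagged = preprocess_document(
            Document("d1", "Steroids reduce rejection.", "Acute rejection was reduced.", "included")
        )
        title_ref = tagged.sentences[0].ref
        abs_ref = tagged.sentences[1].ref
        tagged.spans = [
            SpanAnnotation("I", title_ref, 0, 1),
            SpanAnnotation("O", abs_ref, 0, 2),
            SpanAnnotation("O.Pain", abs_ref, 1, 2),
        ]
        return tagged

    def test_jsonl_round_trip(self, tmp_path):
        tagged = self._tagged()
        path = tmp_path / "corpus.jsonl"
        write_annotated_corpus([tagged], path, format="jsonl")
        (back,) = read_annotated_corpus(path, format="jsonl")
        assert back.document == tagged.document
        assert back.sentences == tagged.sentences
        assert {s.key() for s in back.spans} == {s.key() for s in tagged.spans}

    def test_standoff_round_trip(self, tmp_path):
        tagged = self._tagged()
        out = tmp_path / "standoff"
        write_annotated_corpus([tagged], out, format="standoff")
        ann = (out / "d1.ann").read_text()
        assert "O_Pain" in ann and "\tI " in ann
        (back,) = read_annotated_corpus(out, format="standoff")
        # standoff drops labels but must preserve spans exactly
        assert {s.key() for s in back.spans} == {
            (s.sentence_ref, s.category, s.token_start, s.token_end) for s in tagged.spans
        }

    def test_empty_ann_file(self, tmp_path):
        tagged = self._tagged()
        tagged.spans = []
        out = tmp_path / "standoff"
        write_annotated_corpus([tagged], out, format="standoff")
        (back,) = read_annotated_corpus(out, format="standoff")
        assert back.spans == []

    def test_unknown_category_rejected(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        tagged = self._tagged()
        write_annotated_corpus([tagged], path, format="jsonl")
        bad = path.read_text().replace('"category": "I"', '"category": "X"')
        path.write_text(bad)
        with pytest.raises(Exception, match="[Uu]nknown"):
            read_annotated_corpus(path, format="jsonl")


class TestOffsetIntegrity:
    def test_tokens_index_into_sentence_text(self):
        doc = Document("d", "Beta blockers: a review.", "Half received placebo. Outcomes improved.")
        tagged = preprocess_document(doc)
        assert len(tagged.sentences_for("abstract")) == 2
        for sent in tagged.sentences:
            for tok in sent.tokens:
                assert sent.text[tok.char_start : tok.char_end] == tok.surface
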