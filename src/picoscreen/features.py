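"""Classifier representation: baseline and PICO bag-of-words groups plus LDA topics.

The baseline representation of a reference is three groups — a binary,
L2-normalised bag of title lemmata, another for title and abstract combined,
and the L2-normalised LDA topic proportions.  The PICO representation adds
three more bags holding the lemmata recognised inside Patient, Intervention
and Outcome spans (sharing the title+abstract vocabulary, so PICO bags are
support-subsets of the combined bag).  Empty bags stay zero vectors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma

from picoscreen.pico_tagger.categories import map_to_coarse, parent_category
from picoscreen.textprep import (
    TaggedDocument,
    filter_bow_lemmata,
    load_stopwords,
)

__all__ = [
    "Vocabulary",
    "TopicModelConfig",
    "TopicModel",
    "FeatureVector",
    "GROUP_ORDER",
    "build_vocab",
    "build_bow",
    "build_pico_bows",
    "lda_token_filter",
    "fit_topic_model",
    "infer_topics",
    "assemble_features",
    "build_feature_matrix",
    "save_feature_matrix",
    "load_feature_matrix",
]

GROUP_ORDER = ("bow_title", "bow_titleabs", "bow_P", "bow_I", "bow_O", "topics")
BASELINE_GROUPS = ("bow_title", "bow_titleabs", "topics")


@dataclass(frozen=True)
class Vocabulary:
    """Ordered lemma -> column map built from a collection's own text."""

    index: dict[str, int]
    source: str

    def __len__(self) -> int:
        return len(self.index)

    @property
    def lemmata(self) -> list[str]:
        return sorted(self.index, key=self.index.get)


def _doc_lemmata(tagged: TaggedDocument, context: str, stopwords) -> set[str]:
    fields = ("title",) if context == "title" else ("title", "abstract")
    tokens = [
        t for s in tagged.sentences if s.ref.field in fields for t in s.tokens
    ]
    return filter_bow_lemmata(tokens, stopwords)


def build_vocab(tagged_docs: list[TaggedDocument], context: str = "titleabs") -> Vocabulary:
    """Union of filtered lemmata over all documents, lexicographically ordered.

    Labels are never consulted, so the vocabulary introduces no leakage into
    screening simulations.
    """
    if context not in ("title", "titleabs"):
        raise ValueError(f"unknown vocabulary context {context!r}")
    stopwords = load_stopwords()
    lemmata: set[str] = set()
    for tagged in tagged_docs:
        lemmata |= _doc_lemmata(tagged, context, stopwords)
    if not lemmata:
        raise ValueError("empty vocabulary: no usable lemmata in the collection")
    return Vocabulary({w: i for i, w in enumerate(sorted(lemmata))}, context)


def build_bow(lemma_set: set[str], vocab: Vocabulary) -> sp.csr_matrix:
    """Sparse binary-then-normalised row vector: 1/sqrt(m) per present lemma.

    The zero vector is returned (not normalised) when no lemma is in
    vocabulary.
    """
    cols = sorted(vocab.index[w] for w in lemma_set if w in vocab.index)
    row = sp.lil_matrix((1, len(vocab)))
    if cols:
        row[0, cols] = 1.0 / np.sqrt(len(cols))
    return row.tocsr()


def build_pico_bows(tagged: TaggedDocument) -> dict[str, set[str]]:
    """Lemma sets covered by P, I and O spans (after coarse mapping).

    A token inside nested spans of different categories contributes to both
    bags; span words remain in the general bags too.
    """
    stopwords = load_stopwords()
    out: dict[str, set[str]] = {"P": set(), "I": set(), "O": set()}
    coarse = map_to_coarse(tagged.spans)
    by_ref: dict = {}
    for span in coarse:
        by_ref.setdefault(span.sentence_ref, []).append(span)
    for sent in tagged.sentences:
        for span in by_ref.get(sent.ref, []):
            tokens = sent.tokens[span.token_start : span.token_end]
            out[parent_category(span.category)] |= filter_bow_lemmata(tokens, stopwords)
    return out


# ---------------------------------------------------------------------------
# LDA topics (collapsed Gibbs sampling with alpha re-optimisation)
# ---------------------------------------------------------------------------

# The LDA token filter is deliberately different from the BOW filter: words
# made of alphabetic characters with optional initial or internal punctuation
# (no digits, and not ending in punctuation), minus stop words.
# optional initial punctuation, then letter runs joined by internal
# punctuation, ending in a letter
_LDA_TOKEN_RE = re.compile(r"[\W_]?[^\W\d_]+(?:[\W_]+[^\W\d_]+)*", re.UNICODE)


def lda_token_filter(surface: str, stopwords) -> str | None:
    """Lowercased token if it passes the topic-model filter, else None."""
    w = surface.lower()
    if _LDA_TOKEN_RE.fullmatch(w) is None or w in stopwords:
        return None
    return w


@dataclass
class TopicModelConfig:
    """LDA settings: k topics, symmetric init alpha=1/k, beta=1/100,
    hyperparameter optimisation every 50 Gibbs iterations."""

    k: int = 300
    alpha: float | None = None  # None -> 1/k
    beta: float = 1.0 / 100.0
    optimise_interval: int = 50
    n_iterations: int = 1000
    infer_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if (self.alpha is not None and self.alpha <= 0) or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    def initial_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 1.0 / self.k


@dataclass
class TopicModel:
    """A fitted LDA model: counts, (possibly asymmetric) alpha, and vocabulary."""

    config: TopicModelConfig
    vocab: dict[str, int]
    topic_word: np.ndarray  # (k, V) counts
    topic_totals: np.ndarray  # (k,)
    doc_topic: np.ndarray  # (D, k) counts for the training documents
    alpha: np.ndarray  # (k,)
    doc_ids: list[str]

    @property
    def k(self) -> int:
        return self.config.k


def _doc_lda_tokens(tagged: TaggedDocument, stopwords) -> list[str]:
    words = []
    for sent in tagged.sentences:
        for tok in sent.tokens:
            w = lda_token_filter(tok.surface, stopwords)
            if w is not None:
                words.append(w)
    return words


def _optimise_alpha(alpha: np.ndarray, doc_topic: np.ndarray, n_iter: int = 20) -> np.ndarray:
    """Minka fixed-point update of an asymmetric Dirichlet alpha (MALLET-style)."""
    doc_len = doc_topic.sum(axis=1)
    for _ in range(n_iter):
        a_sum = alpha.sum()
        num = digamma(doc_topic + alpha).sum(axis=0) - len(doc_topic) * digamma(alpha)
        den = digamma(doc_len + a_sum).sum() - len(doc_topic) * digamma(a_sum)
        if den <= 0:
            break
        alpha = np.clip(alpha * num / den, 1e-8, None)
    return alpha


def fit_topic_model(
    tagged_docs: list[TaggedDocument], config: TopicModelConfig | None = None
) -> TopicModel:
    """Fit LDA by collapsed Gibbs sampling over title+abstract tokens.

    Tokens pass the LDA-specific filter (alphabetic with optional initial or
    internal punctuation, not stop words).  Alpha is re-optimised every
    ``optimise_interval`` iterations and may become asymmetric.  Fully
    seeded.
    """
    import warnings

    config = config or TopicModelConfig()
    stopwords = load_stopwords()
    docs_words = [_doc_lda_tokens(t, stopwords) for t in tagged_docs]
    vocab: dict[str, int] = {}
    for words in docs_words:
        for w in words:
            if w not in vocab:
                vocab[w] = len(vocab)
    if not vocab:
        raise ValueError("no tokens pass the LDA filter; cannot fit a topic model")
    if len(tagged_docs) < config.k:
        warnings.warn(
            f"fitting {config.k} topics on only {len(tagged_docs)} documents",
            stacklevel=2,
        )
    V = len(vocab)
    k = config.k
    rng = np.random.default_rng(config.seed)
    docs = [np.array([vocab[w] for w in words], dtype=int) for words in docs_words]

    alpha = np.full(k, config.initial_alpha())
    beta = config.beta
    topic_word = np.zeros((k, V))
    topic_totals = np.zeros(k)
    doc_topic = np.zeros((len(docs), k))
    assignments = []
    for d, ids in enumerate(docs):
        z = rng.integers(0, k, size=len(ids))
        assignments.append(z)
        for w, t in zip(ids, z):
            topic_word[t, w] += 1
            topic_totals[t] += 1
            doc_topic[d, t] += 1

    for it in range(config.n_iterations):
        for d, ids in enumerate(docs):
            z = assignments[d]
            for n, w in enumerate(ids):
                t = z[n]
                topic_word[t, w] -= 1
                topic_totals[t] -= 1
                doc_topic[d, t] -= 1
                p = (doc_topic[d] + alpha) * (topic_word[:, w] + beta) / (topic_totals + V * beta)
                cp = np.cumsum(p)
                t = int(np.searchsorted(cp, rng.random() * cp[-1]))
                z[n] = t
                topic_word[t, w] += 1
                topic_totals[t] += 1
                doc_topic[d, t] += 1
        if config.optimise_interval and (it + 1) % config.optimise_interval == 0:
            alpha = _optimise_alpha(alpha, doc_topic)

    return TopicModel(
        config=config,
        vocab=vocab,
        topic_word=topic_word,
        topic_totals=topic_totals,
        doc_topic=doc_topic,
        alpha=alpha,
        doc_ids=[t.document.id for t in tagged_docs],
    )


def _theta(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    theta = counts + alpha
    theta /= theta.sum()
    norm = np.linalg.norm(theta)
    return theta / norm


def infer_topics(
    tagged: TaggedDocument,
    model: TopicModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """L2-normalised topic proportions for a document.

    Training documents reuse their Gibbs counts; unseen documents are folded
    in with ``config.infer_iterations`` sampling passes against the fixed
    topic-word counts.  A document with no in-model tokens gets a zero
    vector.
    """
    if tagged.document.id in model.doc_ids:
        d = model.doc_ids.index(tagged.document.id)
        if model.doc_topic[d].sum() > 0:
            return _theta(model.doc_topic[d].astype(float), model.alpha)
        return np.zeros(model.k)
    stopwords = load_stopwords()
    ids = np.array(
        [model.vocab[w] for w in _doc_lda_tokens(tagged, stopwords) if w in model.vocab],
        dtype=int,
    )
    if len(ids) == 0:
        return np.zeros(model.k)
    rng = rng or np.random.default_rng(model.config.seed + 1)
    V = len(model.vocab)
    beta = model.config.beta
    word_given_topic = (model.topic_word + beta) / (model.topic_totals + V * beta)[:, None]
    counts = np.zeros(model.k)
    z = rng.integers(0, model.k, size=len(ids))
    for t in z:
        counts[t] += 1
    for _ in range(model.config.infer_iterations):
        for n, w in enumerate(ids):
            counts[z[n]] -= 1
            p = (counts + model.alpha) * word_given_topic[:, w]
            cp = np.cumsum(p)
            z[n] = int(np.searchsorted(cp, rng.random() * cp[-1]))
            counts[z[n]] += 1
    return _theta(counts, model.alpha)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """Named sparse groups for one document, concatenated in ``GROUP_ORDER``."""

    doc_id: str
    groups: dict[str, sp.csr_matrix]
    mode: str

    def concat(self) -> sp.csr_matrix:
        order = BASELINE_GROUPS if self.mode == "baseline" else GROUP_ORDER
        return sp.hstack([self.groups[g] for g in order], format="csr")


def assemble_features(
    tagged: TaggedDocument,
    topic_vector: np.ndarray,
    vocab_title: Vocabulary,
    vocab_titleabs: Vocabulary,
    mode: str = "pico",
) -> FeatureVector:
    """Assemble one document's feature vector.

    ``baseline`` mode has groups (bow_title, bow_titleabs, topics); ``pico``
    mode adds (bow_P, bow_I, bow_O) built over the title+abstract vocabulary.
    """
    if mode not in ("baseline", "pico"):
        raise ValueError(f"unknown feature mode {mode!r}")
    stopwords = load_stopwords()
    groups = {
        "bow_title": build_bow(_doc_lemmata(tagged, "title", stopwords), vocab_title),
        "bow_titleabs": build_bow(
            _doc_lemmata(tagged, "titleabs", stopwords), vocab_titleabs
        ),
        "topics": sp.csr_matrix(np.asarray(topic_vector, dtype=float)[None, :]),
    }
    if mode == "pico":
        pico_sets = build_pico_bows(tagged)
        for cat in ("P", "I", "O"):
            groups[f"bow_{cat}"] = build_bow(pico_sets[cat], vocab_titleabs)
    return FeatureVector(tagged.document.id, groups, mode)


def build_feature_matrix(
    tagged_docs: list[TaggedDocument],
    mode: str = "pico",
    topic_config: TopicModelConfig | None = None,
    topic_model: TopicModel | None = None,
) -> tuple[sp.csr_matrix, dict]:
    """Feature matrix for a whole collection (rows follow document order).

    The vocabularies and the topic model are fitted on the collection's own
    text without consulting labels, so the representation can be fixed once
    before any screening simulation.
    """
    vocab_title = build_vocab(tagged_docs, "title")
    vocab_titleabs = build_vocab(tagged_docs, "titleabs")
    if topic_model is None:
        topic_model = fit_topic_model(tagged_docs, topic_config)
    rows = []
    for tagged in tagged_docs:
        theta = infer_topics(tagged, topic_model)
        rows.append(
            assemble_features(tagged, theta, vocab_title, vocab_titleabs, mode).concat()
        )
    X = sp.vstack(rows, format="csr")
    meta = {
        "mode": mode,
        "doc_ids": [t.document.id for t in tagged_docs],
        "groups": list(BASELINE_GROUPS if mode == "baseline" else GROUP_ORDER),
        "group_dims": {
            "bow_title": len(vocab_title),
            "bow_titleabs": len(vocab_titleabs),
            "bow_P": len(vocab_titleabs) if mode == "pico" else 0,
            "bow_I": len(vocab_titleabs) if mode == "pico" else 0,
            "bow_O": len(vocab_titleabs) if mode == "pico" else 0,
            "topics": topic_model.k,
        },
        "vocab_title": vocab_title.lemmata,
        "vocab_titleabs": vocab_titleabs.lemmata,
    }
    return X, meta


def save_feature_matrix(X: sp.csr_matrix, meta: dict, prefix: str | Path) -> None:
    """Persist features as MTX plus a JSON sidecar naming groups and vocabularies."""
    from scipy.io import mmwrite

    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), X)
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_feature_matrix(prefix: str | Path) -> tuple[sp.csr_matrix, dict]:
    from scipy.io import mmread

    prefix = Path(prefix)
    X = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    meta = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
    return X, meta
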