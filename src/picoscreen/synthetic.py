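"""Synthetic corpora and screening collections with planted structure.

Two generators make the whole pipeline testable without external data:

* :func:`generate_annotated_corpus` emits abstracts whose sentences carry
  nested category spans drawn from role-specific sub-vocabularies (an
  intervention span may be embedded inside a population span, and
  fine-grained sub-spans inside top-level spans), with the planted spans
  recorded as ground truth;
* :func:`generate_screening_collection` emits a labelled collection whose
  inclusion labels follow a logistic model over planted lemma indicators —
  a lemma can contribute to the log-odds only when it occurs inside a span
  of a given category, so that context-restricted occurrence is genuinely
  more predictive than unrestricted occurrence.  The intercept is
  calibrated by bisection to hit a target prevalence in expectation.

Both generators are fully deterministic given their seed.  Vocabularies are
letter-only nonsense words (e.g. ``patabx``), which keeps one word per
token under the rule-based preprocessor and avoids digit-normalisation
collisions in the tagger vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit as sigmoid

from picoscreen.pico_tagger.iob import SpanAnnotation
from picoscreen.textprep import (
    Collection,
    Document,
    SentenceRef,
    TaggedDocument,
    preprocess_document,
)

__all__ = [
    "GrammarConfig",
    "RelevanceConfig",
    "PlantedLemma",
    "default_planted",
    "stats_study_planted",
    "stats_study_config",
    "generate_annotated_corpus",
    "generate_screening_collection",
]


def _letters(i: int) -> str:
    """Deterministic letter-only id: 0 -> 'a', 25 -> 'z', 26 -> 'ba', ..."""
    s = ""
    i = int(i)
    while True:
        s = chr(ord("a") + i % 26) + s
        i //= 26
        if i == 0:
            return s


_ROLE_PREFIX = {"P": "pat", "I": "int", "O": "out"}


def _role_word(cat: str, i: int) -> str:
    return f"{_ROLE_PREFIX[cat]}{_letters(i)}x"


def _fine_word(fine_cat: str, i: int) -> str:
    parent, _, name = fine_cat.partition(".")
    code = "".join(c for c in name.lower() if c.isalpha())[:4]
    return f"{parent.lower()}{code}{_letters(i)}x"


def _bg_word(i: int) -> str:
    return f"bg{_letters(i)}x"


@dataclass
class GrammarConfig:
    """Settings for the annotated-corpus grammar."""

    n_documents: int = 60
    sentences_per_abstract: tuple[int, int] = (2, 3)  # inclusive range
    sentence_len: tuple[int, int] = (7, 11)
    n_background_words: int = 120
    n_role_words: int = 25  # per top-level category
    n_fine_words: int = 10  # per fine-grained type used
    fine_types: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "P": ("Condition",),
            "I": ("Pharmacological",),
            "O": ("Pain",),
        }
    )
    span_prob: float = 0.8  # probability a sentence carries a top-level span
    extra_span_prob: float = 0.35  # chance of a second top-level span
    nesting_prob: float = 0.25  # I span embedded inside a P span
    fine_prob: float = 0.5  # fine-grained sub-span inside a top-level span
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.span_prob, self.extra_span_prob, self.nesting_prob, self.fine_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.n_background_words, self.n_role_words, self.n_documents) < 1:
            raise ValueError("vocabulary sizes and n_documents must be >= 1")


def _sample_sentence(rng: np.random.Generator, cfg: GrammarConfig):
    """One sentence: word list plus (category, start, end) span tuples."""
    length = int(rng.integers(cfg.sentence_len[0], cfg.sentence_len[1] + 1))
    words = [_bg_word(rng.integers(cfg.n_background_words)) for _ in range(length)]
    spans: list[tuple[str, int, int]] = []
    if rng.random() >= cfg.span_prob:
        return words, spans
    n_spans = 2 if rng.random() < cfg.extra_span_prob and length >= 9 else 1
    cursor = 0
    for _ in range(n_spans):
        max_len = 4
        if length - cursor < max_len + 1:
            break
        cat = ("P", "I", "O")[rng.integers(3)]
        nested = cat == "P" and rng.random() < cfg.nesting_prob
        span_len = int(rng.integers(3, max_len + 1)) if nested else int(rng.integers(2, max_len))
        start = cursor + int(rng.integers(0, length - cursor - span_len + 1))
        end = start + span_len
        for k in range(start, end):
            words[k] = _role_word(cat, rng.integers(cfg.n_role_words))
        spans.append((cat, start, end))
        if nested:
            # an intervention mention inside the population span
            inner_len = int(rng.integers(1, span_len - 1 + 1))
            inner_start = start + int(rng.integers(0, span_len - inner_len + 1))
            for k in range(inner_start, inner_start + inner_len):
                words[k] = _role_word("I", rng.integers(cfg.n_role_words))
            spans.append(("I", inner_start, inner_start + inner_len))
        elif cfg.fine_types.get(cat) and rng.random() < cfg.fine_prob and span_len >= 2:
            fines = cfg.fine_types[cat]
            fine = f"{cat}.{fines[rng.integers(len(fines))]}"
            inner_len = int(rng.integers(1, span_len))
            inner_start = start + int(rng.integers(0, span_len - inner_len + 1))
            for k in range(inner_start, inner_start + inner_len):
                words[k] = _fine_word(fine, rng.integers(cfg.n_fine_words))
            spans.append((fine, inner_start, inner_start + inner_len))
        cursor = end + 1
    return words, spans


def _assemble_document(
    doc_id: str,
    title_words: list[str],
    abstract_sentences: list[tuple[list[str], list]],
    label: str = "unlabelled",
) -> TaggedDocument:
    """Build text, preprocess it, and attach spans at token level."""
    title = " ".join(title_words).capitalize()
    abstract = " ".join(
        " ".join(words).capitalize() + "." for words, _ in abstract_sentences
    )
    doc = Document(id=doc_id, title=title, abstract=abstract, label=label)
    tagged = preprocess_document(doc)
    for idx, (words, spans) in enumerate(abstract_sentences):
        ref = SentenceRef(doc_id, "abstract", idx)
        sent = tagged.sentence(ref)
        if len(sent.tokens) != len(words) + 1:  # words plus final period
            raise AssertionError("generator/preprocessor token misalignment")
        for cat, start, end in spans:
            tagged.spans.append(SpanAnnotation(cat, ref, start, end))
    return tagged


def generate_annotated_corpus(config: GrammarConfig | None = None) -> list[TaggedDocument]:
    """Sample an annotated corpus with planted (possibly nested) spans."""
    cfg = config or GrammarConfig()
    rng = np.random.default_rng(cfg.seed)
    corpus = []
    for d in range(cfg.n_documents):
        title_words = [_bg_word(rng.integers(cfg.n_background_words)) for _ in range(5)]
        n_sent = int(
            rng.integers(cfg.sentences_per_abstract[0], cfg.sentences_per_abstract[1] + 1)
        )
        sentences = [_sample_sentence(rng, cfg) for _ in range(n_sent)]
        corpus.append(_assemble_document(f"syn{d:04d}", title_words, sentences))
    return corpus


# ---------------------------------------------------------------------------
# Screening collections with context-dependent relevance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedLemma:
    """A lemma with a context-specific log-odds contribution.

    ``beta_context`` is added to a document's inclusion log-odds when the
    lemma occurs inside a span of ``context`` ("P"/"I"/"O"), and
    ``beta_bow`` whenever it occurs anywhere.  ``p_occur`` is the chance the
    lemma appears in a document at all; given occurrence, ``p_in_context``
    is the chance it is placed inside its context span rather than in
    background text.
    """

    lemma: str
    context: str = "O"
    beta_context: float = 5.0
    beta_bow: float = 0.0
    p_occur: float = 0.3
    p_in_context: float = 0.2


def default_planted() -> list[PlantedLemma]:
    """Five outcome-context keywords whose relevancy is context-dependent.

    Only one occurrence in five sits inside an outcome span, so the
    unrestricted bag-of-words indicator is heavily diluted while the
    context-restricted indicator is close to decisive (log-odds +5) —
    the regime in which PICO-restricted features genuinely add signal.
    """
    return [PlantedLemma(f"key{_letters(j)}x", context="O") for j in range(5)]


def stats_study_planted() -> list[PlantedLemma]:
    """Planted lemmata for the context-word statistics study.

    Stronger and rarer than the screening defaults: an occurrence inside an
    outcome span is close to decisive for inclusion (log-odds +6), while
    out-of-context occurrences are common enough (60% of occurrences) to
    dilute the unrestricted PPV.  This mirrors keyword-driven reviews where
    outcome terms are strong inclusion signals only in outcome position.
    """
    return [
        PlantedLemma(
            f"key{_letters(j)}x",
            context="O",
            beta_context=6.0,
            p_occur=0.12,
            p_in_context=0.4,
        )
        for j in range(5)
    ]


def stats_study_config(seed: int = 0) -> "RelevanceConfig":
    """Collection for the dual-test selection study.

    Larger and with higher prevalence than the screening default (800
    references at 15% inclusions, comparable to the denser drug-class
    reviews): document-level presence tests at a 0.01 significance level
    need on the order of 20 true-positive documents per word, which a
    20-inclusion collection cannot supply.
    """
    return RelevanceConfig(
        n_documents=800,
        prevalence=0.15,
        planted=stats_study_planted(),
        seed=seed,
        name="synthetic-stats-study",
    )


@dataclass
class RelevanceConfig:
    """Settings for a screening collection with context-dependent relevance."""

    n_documents: int = 400
    prevalence: float = 0.05
    planted: list[PlantedLemma] = field(default_factory=default_planted)
    sentence_len: tuple[int, int] = (8, 12)
    n_background_words: int = 150
    n_role_words: int = 20
    seed: int = 0
    name: str = "synthetic-screening"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_documents < 2:
            raise ValueError("need at least 2 documents")


def _calibrate_intercept(etas: np.ndarray, target: float) -> float:
    """Bisection on b so that mean sigmoid(b + eta) hits the target prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if sigmoid(mid + etas).mean() < target:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    if abs(sigmoid(b + etas).mean() - target) > 0.01:
        raise ValueError("target prevalence is not achievable by intercept calibration")
    return b


def generate_screening_collection(
    config: RelevanceConfig | None = None,
) -> tuple[Collection, list[TaggedDocument]]:
    """Sample a labelled collection together with its gold span annotations.

    Every abstract carries one P, one I and one O span.  Planted lemmata are
    written either into their context span or into background positions;
    the inclusion label is drawn from the logistic model over the planted
    indicators.  Returns the collection and the per-document gold
    :class:`TaggedDocument` (labels included), in the same order.
    """
    cfg = config or RelevanceConfig()
    rng = np.random.default_rng(cfg.seed)

    blueprints = []
    etas = np.zeros(cfg.n_documents)
    for d in range(cfg.n_documents):
        sentences = []
        span_by_cat: dict[str, tuple[int, int, int]] = {}  # cat -> (sent_idx, start, end)
        for s_idx, cat in enumerate(("P", "I", "O")):
            length = int(rng.integers(cfg.sentence_len[0], cfg.sentence_len[1] + 1))
            words = [_bg_word(rng.integers(cfg.n_background_words)) for _ in range(length)]
            span_len = int(rng.integers(2, 4))
            start = int(rng.integers(0, length - span_len + 1))
            for k in range(start, start + span_len):
                words[k] = _role_word(cat, rng.integers(cfg.n_role_words))
            sentences.append((words, [(cat, start, start + span_len)]))
            span_by_cat[cat] = (s_idx, start, start + span_len)

        eta = 0.0
        for pl in cfg.planted:
            if rng.random() >= pl.p_occur:
                continue
            in_ctx = pl.context in span_by_cat and rng.random() < pl.p_in_context
            if in_ctx:
                s_idx, start, end = span_by_cat[pl.context]
                pos = start + int(rng.integers(0, end - start))
                sentences[s_idx][0][pos] = pl.lemma
                eta += pl.beta_context + pl.beta_bow
            else:
                # background slot outside every span
                placed = False
                for _ in range(50):
                    s_idx = int(rng.integers(len(sentences)))
                    words, spans = sentences[s_idx]
                    pos = int(rng.integers(len(words)))
                    if all(not (st <= pos < en) for _c, st, en in spans) and words[
                        pos
                    ].startswith("bg"):
                        words[pos] = pl.lemma
                        placed = True
                        break
                if placed:
                    eta += pl.beta_bow
        etas[d] = eta

        title_words = [_bg_word(rng.integers(cfg.n_background_words)) for _ in range(5)]
        blueprints.append((title_words, sentences))

    intercept = _calibrate_intercept(etas, cfg.prevalence)
    labels = rng.random(cfg.n_documents) < sigmoid(intercept + etas)

    tagged_docs = []
    for d, (title_words, sentences) in enumerate(blueprints):
        label = "included" if labels[d] else "excluded"
        tagged_docs.append(
            _assemble_document(f"col{d:04d}", title_words, sentences, label=label)
        )
    collection = Collection(cfg.name, [t.document for t in tagged_docs])
    return collection, tagged_docs
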