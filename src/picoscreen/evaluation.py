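"""Evaluation metrics: recall curves, WSS@95%, tagging P/R/F1, and the sign test.

The screening metric is work saved over sampling at 95% recall,

    WSS@95% = 95% - i_R95 / N,

where ``i_R95`` is the smallest number of screened references at which
recall first reaches 0.95.  Screening in random-expectation order gives
WSS@95% = 0; a perfect ranking of a low-prevalence collection approaches
0.95.

Tagging is scored token-wise per coarse category (set-valued token
membership, micro-aggregated) and at the document level on filtered
bag-of-words lemma sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from picoscreen.pico_tagger.categories import map_to_coarse, parent_category
from picoscreen.textprep import Collection, TaggedDocument, filter_bow_lemmata, load_stopwords

__all__ = [
    "RecallCurve",
    "ScreeningResult",
    "PRF",
    "recall_curve",
    "wss95",
    "f1",
    "span_prf",
    "token_prf",
    "doclevel_bow_prf",
    "prevalence",
    "sign_test",
    "sign_test_from_deltas",
]


@dataclass
class RecallCurve:
    """Cumulative screening counts: TP(i) + FP(i) = i, TP(i) + FN(i) = R."""

    n: int
    r: int
    tp: np.ndarray  # TP(i) for i = 1..N
    recall: np.ndarray

    def fp(self) -> np.ndarray:
        return np.arange(1, self.n + 1) - self.tp

    def fn(self) -> np.ndarray:
        return self.r - self.tp


@dataclass(frozen=True)
class ScreeningResult:
    i_r95: int
    wss95: float


@dataclass
class PRF:
    tp: int
    fp: int
    fn: int
    zero_denominator: bool = False

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def f1(self) -> float:
        return f1(self.precision, self.recall)


def recall_curve(labels_in_order, r: int | None = None) -> RecallCurve:
    """Recall after each screened reference, from the screening order's labels."""
    labels = np.asarray(labels_in_order, dtype=bool)
    total_r = int(labels.sum()) if r is None else r
    if total_r == 0:
        raise ValueError("no relevant references: recall is undefined")
    tp = np.cumsum(labels)
    return RecallCurve(n=len(labels), r=total_r, tp=tp, recall=tp / total_r)


def wss95(curve: RecallCurve) -> ScreeningResult:
    """Smallest i with recall >= 0.95, and the corresponding work saved."""
    reached = np.flatnonzero(curve.recall >= 0.95)
    i_r95 = int(reached[0]) + 1  # i is 1-based
    return ScreeningResult(i_r95=i_r95, wss95=0.95 - i_r95 / curve.n)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def span_prf(gold_keys: set, pred_keys: set) -> PRF:
    """Exact span-level match (category + interval), used for early stopping."""
    tp = len(gold_keys & pred_keys)
    return PRF(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)


def _token_sets(spans) -> dict[str, set]:
    """Per coarse category, the set of (sentence_ref, token_index) members."""
    out: dict[str, set] = {}
    for span in map_to_coarse(spans):
        members = out.setdefault(parent_category(span.category), set())
        for t in range(span.token_start, span.token_end):
            members.add((span.sentence_ref, t))
    return out


def token_prf(gold_docs: list[TaggedDocument], pred_docs: list[TaggedDocument]) -> dict[str, PRF]:
    """Token-wise precision/recall/F1 per coarse category, micro-aggregated.

    A token covered by two nested same-category spans counts once.  True
    positives are tokens of a category's gold span also assigned that
    category by the model; false positives are model-assigned tokens outside
    any gold span of the category.
    """
    counts = {c: PRF(0, 0, 0) for c in ("P", "I", "O")}
    gold_by_id = {t.document.id: t for t in gold_docs}
    for pred in pred_docs:
        gold = gold_by_id.get(pred.document.id)
        if gold is None:
            raise ValueError(f"no gold annotation for document {pred.document.id!r}")
        if [len(s.tokens) for s in gold.sentences] != [len(s.tokens) for s in pred.sentences]:
            raise ValueError(f"tokenisation mismatch for document {pred.document.id!r}")
        g = _token_sets(gold.spans)
        p = _token_sets(pred.spans)
        for cat in counts:
            gset = g.get(cat, set())
            pset = p.get(cat, set())
            counts[cat].tp += len(gset & pset)
            counts[cat].fp += len(pset - gset)
            counts[cat].fn += len(gset - pset)
    for prf in counts.values():
        prf.zero_denominator = prf.tp + prf.fp == 0 or prf.tp + prf.fn == 0
    return counts


def _span_lemmata(tagged: TaggedDocument, stopwords) -> dict[str, set]:
    out: dict[str, set] = {}
    by_ref: dict = {}
    for span in map_to_coarse(tagged.spans):
        by_ref.setdefault(span.sentence_ref, []).append(span)
    for sent in tagged.sentences:
        for span in by_ref.get(sent.ref, []):
            tokens = sent.tokens[span.token_start : span.token_end]
            members = out.setdefault(parent_category(span.category), set())
            members |= filter_bow_lemmata(tokens, stopwords)
    return out


def doclevel_bow_prf(
    gold_docs: list[TaggedDocument], pred_docs: list[TaggedDocument]
) -> dict[str, PRF]:
    """Document-level comparison of filtered span lemma sets per category.

    Measures whether the annotated PICO words would be captured when each
    document is reduced to a filtered bag of lemmata (same filtering as the
    relevancy BOWs).  Documents where both gold and predicted sets are empty
    are skipped; counts are micro-aggregated over documents.
    """
    stopwords = load_stopwords()
    counts = {c: PRF(0, 0, 0) for c in ("P", "I", "O")}
    gold_by_id = {t.document.id: t for t in gold_docs}
    for pred in pred_docs:
        gold = gold_by_id.get(pred.document.id)
        if gold is None:
            raise ValueError(f"no gold annotation for document {pred.document.id!r}")
        g = _span_lemmata(gold, stopwords)
        p = _span_lemmata(pred, stopwords)
        for cat in counts:
            gset = g.get(cat, set())
            pset = p.get(cat, set())
            if not gset and not pset:
                continue
            counts[cat].tp += len(gset & pset)
            counts[cat].fp += len(pset - gset)
            counts[cat].fn += len(gset - pset)
    for prf in counts.values():
        prf.zero_denominator = prf.tp + prf.fp == 0 or prf.tp + prf.fn == 0
    return counts


def prevalence(collection: Collection) -> float:
    """Percentage of included references in a labelled collection."""
    if any(d.label == "unlabelled" for d in collection):
        raise ValueError("prevalence requires a fully labelled collection")
    included = sum(d.label == "included" for d in collection)
    return 100.0 * included / len(collection)


def sign_test(successes: int, n: int) -> float:
    """One-sided exact sign test: P(X >= successes), X ~ Binomial(n, 1/2)."""
    if n <= 0:
        raise ValueError("sign test needs n >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    return float(binom.sf(successes - 1, n, 0.5))


def sign_test_from_deltas(deltas, tie_policy: str = "success") -> tuple[float, int, int]:
    """Sign test over per-collection WSS deltas; returns (p, successes, n).

    ``tie_policy`` controls zero deltas: ``success`` counts them as
    improvements (default), ``drop`` removes them, ``half`` adds half a
    success each (rounded down with n kept).
    """
    deltas = list(deltas)
    pos = sum(d > 0 for d in deltas)
    zero = sum(d == 0 for d in deltas)
    n = len(deltas)
    if tie_policy == "success":
        successes = pos + zero
    elif tie_policy == "drop":
        successes, n = pos, n - zero
    elif tie_policy == "half":
        successes = pos + math.floor(zero / 2)
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return sign_test(successes, n), successes, n
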