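"""Context-restricted word statistics: which lemmata are more precise inside PICO spans?

For every (context, lemma) pair — context being P, I, O or the unrestricted
title+abstract bag — the module counts the included documents containing the
lemma (TP) and the excluded documents containing it (FP), at document-level
binary presence.  Two tests gate the selection of PICO-predictive words:

* Pearson's chi-squared test of independence between context-restricted
  presence and the inclusion label (no continuity correction, df = 1);
* a generalised score test for equality of positive predictive values of
  the paired "tests" (context-restricted vs unrestricted occurrence), built
  as a working-independence score statistic with a cluster-robust variance,
  clustering the per-(document, context) records by document.

A (context, lemma) pair is selected when both tests fall below the
significance level (0.01 by default, no multiplicity correction) and the
context-restricted PPV exceeds the unrestricted PPV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import chi2_contingency

from picoscreen.features import Vocabulary, build_pico_bows
from picoscreen.textprep import TaggedDocument, filter_bow_lemmata, load_stopwords

__all__ = [
    "ContextWordCounts",
    "TestResult",
    "count_context_occurrences",
    "ppv",
    "chi2_independence",
    "gs_ppv_test",
    "select_pico_predictive",
]

CONTEXTS = ("P", "I", "O", "BOW")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    test_name: str
    degenerate: bool = False


@dataclass
class ContextWordCounts:
    """Document-level presence counts for one lemma in one context.

    ``doc_ids``, ``in_context``, ``in_bow`` and ``label`` are aligned
    per-document indicator arrays over documents where the lemma occurs
    anywhere (so context presence implies bag presence).
    """

    context: str
    lemma: str
    tp: int
    fp: int
    doc_ids: list[str]
    in_context: np.ndarray
    in_bow: np.ndarray
    label: np.ndarray


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP / (TP + FP)."""
    if tp + fp < 1:
        raise ValueError("PPV undefined: no document contains the feature")
    return tp / (tp + fp)


def count_context_occurrences(
    tagged_docs: list[TaggedDocument], vocab: Vocabulary | None = None
) -> dict[tuple[str, str], ContextWordCounts]:
    """Per (context, lemma) document-presence counts with paired indicators.

    Presence is binary at the document level.  Lemmata are restricted to
    ``vocab`` when given, otherwise every filtered lemma is counted.  All
    documents must be labelled.
    """
    stopwords = load_stopwords()
    presence: dict[tuple[str, str], dict] = {}
    n_docs = len(tagged_docs)
    doc_ids = []
    labels = np.zeros(n_docs, dtype=bool)
    bow_presence: dict[str, np.ndarray] = {}
    ctx_presence: dict[tuple[str, str], np.ndarray] = {}

    for d, tagged in enumerate(tagged_docs):
        doc = tagged.document
        if doc.label == "unlabelled":
            raise ValueError(f"document {doc.id!r} is unlabelled")
        doc_ids.append(doc.id)
        labels[d] = doc.label == "included"
        tokens = [t for s in tagged.sentences for t in s.tokens]
        bow = filter_bow_lemmata(tokens, stopwords)
        pico = build_pico_bows(tagged)
        if vocab is not None:
            bow &= set(vocab.index)
            pico = {c: s & set(vocab.index) for c, s in pico.items()}
        for lemma in bow:
            bow_presence.setdefault(lemma, np.zeros(n_docs, dtype=bool))[d] = True
        for ctx in ("P", "I", "O"):
            for lemma in pico[ctx]:
                ctx_presence.setdefault((ctx, lemma), np.zeros(n_docs, dtype=bool))[d] = True

    out: dict[tuple[str, str], ContextWordCounts] = {}
    for lemma, in_bow in bow_presence.items():
        docs_mask = in_bow  # lemma occurs somewhere in these documents
        idx = np.flatnonzero(docs_mask)
        base = dict(
            doc_ids=[doc_ids[i] for i in idx],
            in_bow=in_bow[idx],
            label=labels[idx],
        )
        out[("BOW", lemma)] = ContextWordCounts(
            context="BOW",
            lemma=lemma,
            tp=int(np.sum(labels & in_bow)),
            fp=int(np.sum(~labels & in_bow)),
            in_context=in_bow[idx].copy(),
            **base,
        )
        for ctx in ("P", "I", "O"):
            ctx_mask = ctx_presence.get((ctx, lemma))
            if ctx_mask is None or not ctx_mask.any():
                continue
            out[(ctx, lemma)] = ContextWordCounts(
                context=ctx,
                lemma=lemma,
                tp=int(np.sum(labels & ctx_mask)),
                fp=int(np.sum(~labels & ctx_mask)),
                in_context=ctx_mask[idx],
                **base,
            )
    return out


def chi2_independence(tp: int, fp: int, n_included: int, n_excluded: int) -> TestResult:
    """Pearson chi-squared (no continuity correction) on presence x label."""
    table = np.array([[tp, fp], [n_included - tp, n_excluded - fp]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts exceed class totals")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult(0.0, 1, 1.0, "pearson_chi2", degenerate=True)
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return TestResult(float(stat), int(dof), float(p), "pearson_chi2")


def gs_ppv_test(counts_context: ContextWordCounts, counts_bow: ContextWordCounts) -> TestResult:
    """Generalised score test for equal PPV of paired context-restricted vs
    unrestricted occurrence.

    One record is created per (document, occurrence type) where the type is
    positive; ``x`` marks the restricted type and ``d`` the inclusion label.
    With record means ``x_bar, d_bar``, the score is
    ``S = sum (x - x_bar)(d - d_bar)`` and the variance is cluster-robust
    over documents, ``V = sum_doc [sum_records (x - x_bar)(d - d_bar)]^2``;
    the statistic ``S^2 / V`` is referred to chi-squared with 1 df.
    """
    if counts_context.lemma != counts_bow.lemma:
        raise ValueError("paired counts must concern the same lemma")
    if np.any(counts_context.in_context & ~counts_context.in_bow):
        raise ValueError("context-restricted presence must imply unrestricted presence")
    xs, ds, cluster = [], [], []
    for i in range(len(counts_context.doc_ids)):
        d = float(counts_context.label[i])
        if counts_context.in_bow[i]:
            xs.append(0.0)
            ds.append(d)
            cluster.append(i)
        if counts_context.in_context[i]:
            xs.append(1.0)
            ds.append(d)
            cluster.append(i)
    xs = np.asarray(xs)
    ds = np.asarray(ds)
    cluster = np.asarray(cluster)
    xc = xs - xs.mean()
    dc = ds - ds.mean()
    s = float(np.sum(xc * dc))
    per_cluster = np.zeros(len(counts_context.doc_ids))
    np.add.at(per_cluster, cluster, xc * dc)
    v = float(np.sum(per_cluster**2))
    if v <= 0.0:
        return TestResult(0.0, 1, 1.0, "gs_ppv", degenerate=True)
    stat = s * s / v
    return TestResult(stat, 1, float(chi2_dist.sf(stat, 1)), "gs_ppv")


@dataclass
class SelectionRow:
    context: str
    lemma: str
    tp: int
    fp: int
    ppv_context: float
    ppv_bow: float
    chi2: TestResult
    gs: TestResult
    selected: bool


def select_pico_predictive(
    counts: dict[tuple[str, str], ContextWordCounts],
    alpha: float = 0.01,
    bonferroni: bool = False,
    n_included: int | None = None,
    n_excluded: int | None = None,
) -> list[SelectionRow]:
    """Dual-test selection of PICO-predictive (context, lemma) pairs.

    Selected iff the context chi-squared p-value and the generalised score
    p-value both fall below ``alpha`` and the context PPV exceeds the
    unrestricted PPV.  No multiplicity correction by default; ``bonferroni``
    divides ``alpha`` by the number of tested pairs.  Rows are sorted by
    chi-squared statistic, descending.  Class totals default to the labelled
    documents seen in ``counts``.
    """
    rows: list[SelectionRow] = []
    tested = [key for key in counts if key[0] != "BOW"]
    level = alpha / max(len(tested), 1) if bonferroni else alpha
    if n_included is None or n_excluded is None:
        all_labels: dict[str, bool] = {}
        for c in counts.values():
            for doc_id, lab in zip(c.doc_ids, c.label):
                all_labels[doc_id] = bool(lab)
        n_included = sum(all_labels.values())
        n_excluded = len(all_labels) - n_included
    for ctx, lemma in tested:
        c = counts[(ctx, lemma)]
        bow = counts.get(("BOW", lemma))
        if bow is None:
            continue
        chi2_res = chi2_independence(c.tp, c.fp, n_included, n_excluded)
        gs_res = gs_ppv_test(c, bow)
        ppv_ctx = ppv(c.tp, c.fp)
        ppv_bow = ppv(bow.tp, bow.fp)
        rows.append(
            SelectionRow(
                context=ctx,
                lemma=lemma,
                tp=c.tp,
                fp=c.fp,
                ppv_context=ppv_ctx,
                ppv_bow=ppv_bow,
                chi2=chi2_res,
                gs=gs_res,
                selected=(
                    chi2_res.p_value < level
                    and gs_res.p_value < level
                    and ppv_ctx > ppv_bow
                ),
            )
        )
    rows.sort(key=lambda r: -r.chi2.statistic)
    return rows
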