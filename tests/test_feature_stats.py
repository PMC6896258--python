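"""Context-word statistics: PPV, chi-squared, the GS test and dual-test selection."""

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from picoscreen.feature_stats import (
    ContextWordCounts,
    chi2_independence,
    count_context_occurrences,
    gs_ppv_test,
    ppv,
    select_pico_predictive,
)
from picoscreen.pico_tagger import SpanAnnotation
from picoscreen.synthetic import stats_study_planted
from picoscreen.textprep import Document, preprocess_document


class TestPpv:
    @pytest.mark.parametrize(
        "tp,fp,expected", [(96, 46, 0.68), (49, 14, 0.78), (40, 10, 0.80), (21, 78, 0.21)]
    )
    def test_reported_table_values(self, tp, fp, expected):
        assert round(ppv(tp, fp), 2) == expected

    def test_zero_tp(self):
        assert ppv(0, 5) == 0.0

    def test_undefined_without_occurrences(self):
        with pytest.raises(ValueError):
            ppv(0, 0)

    def test_monotone_in_tp(self):
        values = [ppv(tp, 50 - tp) for tp in range(51)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestChi2:
    def test_independence_gives_zero(self):
        res = chi2_independence(10, 10, 20, 20)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_association(self):
        assert chi2_independence(30, 10, 40, 40).statistic == pytest.approx(20.0)

    def test_row_swap_symmetry(self):
        a = chi2_independence(30, 10, 40, 40)
        b = chi2_independence(10, 30, 40, 40)
        assert a.statistic == pytest.approx(b.statistic)

    def test_degenerate_margin_flagged(self):
        res = chi2_independence(0, 0, 10, 10)
        assert res.degenerate and res.p_value == 1.0


def _counts(in_context, in_bow, label):
    in_context = np.asarray(in_context, bool)
    in_bow = np.asarray(in_bow, bool)
    label = np.asarray(label, bool)
    return ContextWordCounts(
        context="O",
        lemma="w",
        tp=int((in_context & label).sum()),
        fp=int((in_context & ~label).sum()),
        doc_ids=[f"d{k}" for k in range(len(label))],
        in_context=in_context,
        in_bow=in_bow,
        label=label,
    )


def _bow_of(c):
    return ContextWordCounts(
        context="BOW",
        lemma=c.lemma,
        tp=int((c.in_bow & c.label).sum()),
        fp=int((c.in_bow & ~c.label).sum()),
        doc_ids=c.doc_ids,
        in_context=c.in_bow,
        in_bow=c.in_bow,
        label=c.label,
    )


def _gs_statistic_brute(in_context, in_bow, label):
    xs, ds, cl = [], [], []
    for i, (a, b, d) in enumerate(zip(in_context, in_bow, label)):
        if b:
            xs.append(0.0), ds.append(float(d)), cl.append(i)
        if a:
            xs.append(1.0), ds.append(float(d)), cl.append(i)
    xs, ds = np.array(xs), np.array(ds)
    xc, dc = xs - xs.mean(), ds - ds.mean()
    s = np.sum(xc * dc)
    per = {}
    for c, v in zip(cl, xc * dc):
        per[c] = per.get(c, 0.0) + v
    v = sum(x * x for x in per.values())
    return s, v


class TestGsTest:
    def test_identical_tests_give_zero(self):
        c = _counts([1, 1, 0, 1], [1, 1, 0, 1], [1, 0, 1, 0])
        res = gs_ppv_test(c, _bow_of(c))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_positive_document_degenerate(self):
        c = _counts([1, 0, 0], [1, 0, 0], [1, 0, 0])
        res = gs_ppv_test(c, _bow_of(c))
        assert res.degenerate

    def test_subset_violation_rejected(self):
        c = _counts([1, 0], [0, 1], [1, 0])
        with pytest.raises(ValueError, match="imply"):
            gs_ppv_test(c, _bow_of(c))

    def test_statistic_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        in_bow = np.ones(30, bool)
        in_context = rng.random(30) < 0.5
        label = rng.random(30) < 0.4
        c = _counts(in_context, in_bow, label)
        res = gs_ppv_test(c, _bow_of(c))
        s, v = _gs_statistic_brute(in_context, in_bow, label)
        assert res.statistic == pytest.approx(s * s / v)
        assert res.p_value == pytest.approx(chi2_dist.sf(s * s / v, 1))


class TestCounting:
    def _tagged(self, title, spans, label):
        doc = preprocess_document(Document("d0", title, "", label))
        ref = doc.sentences[0].ref
        doc.spans = [SpanAnnotation(c, ref, s, e) for c, s, e in spans]
        return doc

    def test_context_occurrence_counted(self):
        doc = self._tagged("Severe migraine pain", [("O", 1, 3)], "included")
        counts = count_context_occurrences([doc])
        assert counts[("O", "pain")].tp == 1 and counts[("O", "pain")].fp == 0

    def test_out_of_span_occurrence_counts_only_in_bow(self):
        doc = self._tagged("Severe migraine pain", [("O", 0, 1)], "excluded")
        counts = count_context_occurrences([doc])
        assert ("O", "pain") not in counts
        assert counts[("BOW", "pain")].fp == 1

    def test_unlabelled_document_rejected(self):
        doc = self._tagged("Severe pain", [], "unlabelled")
        with pytest.raises(ValueError, match="unlabelled"):
            count_context_occurrences([doc])

    def test_subset_invariant_on_synthetic_collection(self, stats_study):
        _, tagged = stats_study
        counts = count_context_occurrences(tagged)
        for (ctx, lemma), c in counts.items():
            assert not np.any(c.in_context & ~c.in_bow)
            assert c.tp + c.fp >= 1


class TestSelection:
    def test_direction_gate(self):
        # strong association but context PPV below unrestricted PPV: never selected
        label = np.array([True] * 30 + [False] * 30)
        in_bow = np.ones(60, bool)
        in_context = np.array([False] * 20 + [True] * 40)  # ppv_ctx 1/4 < ppv_bow 1/2
        c = _counts(in_context, in_bow, label)
        counts = {("O", "w"): c, ("BOW", "w"): _bow_of(c)}
        (row,) = select_pico_predictive(counts)
        assert row.ppv_context < row.ppv_bow and not row.selected

    def test_single_document_lemma_not_selected(self):
        c = _counts([1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0])
        counts = {("O", "w"): c, ("BOW", "w"): _bow_of(c)}
        (row,) = select_pico_predictive(counts)
        assert not row.selected

    def test_planted_context_lemmata_recovered(self, stats_study):
        _, tagged = stats_study
        counts = count_context_occurrences(tagged)
        rows = select_pico_predictive(counts)
        selected = {(r.context, r.lemma) for r in rows if r.selected}
        planted = {("O", p.lemma) for p in stats_study_planted()}
        assert len(planted & selected) >= 4
        assert len(selected - planted) <= 2

    def test_rows_sorted_by_chi2(self, stats_study):
        _, tagged = stats_study
        rows = select_pico_predictive(count_context_occurrences(tagged))
        stats = [r.chi2.statistic for r in rows]
        assert stats == sorted(stats, reverse=True)
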