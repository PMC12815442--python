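"""Tests for the diagnostic statistics, each against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wase.metrics import (
    bootstrap_ci,
    confusion_metrics,
    delong_test,
    hosmer_lemeshow,
    roc_auc,
    roc_curve,
    youden_threshold,
)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: (wins + half ties) over all case-control pairs."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    ctrls = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for c in cases:
        for d in ctrls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(ctrls))


small_instances = st.integers(2, 50).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 10).map(lambda v: v / 10), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < len(y)
        ),
    )
)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_pair_enumeration_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(small_instances)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_equals_brute_force_pair_counting(self, inst):
        scores, labels = inst
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @given(small_instances)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_invariant_under_monotone_transform(self, inst):
        scores, labels = inst
        transformed = [np.expm1(3 * s) for s in scores]
        assert roc_auc(transformed, labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200).round(1)
        labels = rng.integers(0, 2, size=200)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestRocCurveAndYouden:
    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels)
        assert roc.tpr[0] == roc.fpr[0] == 0.0
        assert roc.tpr[-1] == roc.fpr[-1] == 1.0
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.thresholds) < 0).all()

    def test_perfect_separation_attains_j_of_one(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        thr = youden_threshold(roc)
        m = confusion_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], thr)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_all_ties_give_zero_j(self):
        roc = roc_curve([0.3] * 4, [1, 0, 1, 0])
        j = roc.tpr - roc.fpr
        assert np.allclose(j, 0.0)

    def test_exhaustive_cut_point_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        # enumerate every cut point c (positive iff s > c)
        best_j, best = -np.inf, None
        for c in sorted(set(scores) | {-np.inf}, reverse=True):
            tpr = np.mean(scores[labels == 1] > c)
            fpr = np.mean(scores[labels == 0] > c)
            if tpr - fpr > best_j:
                best_j, best = tpr - fpr, c
        thr = youden_threshold(roc_curve(scores, labels))
        m = confusion_metrics(scores, labels, thr)
        assert (m.sensitivity - (1 - m.specificity)) == pytest.approx(best_j)

    def test_tie_break_prefers_higher_sensitivity(self):
        # two cut points share J; the lower-threshold one has higher tpr
        scores = [0.1, 0.2, 0.3, 0.4]
        labels = [0, 1, 0, 1]
        roc = roc_curve(scores, labels)
        j = roc.tpr - roc.fpr
        ties = np.flatnonzero(j == j.max())
        assert len(ties) > 1
        thr = youden_threshold(roc)
        chosen = np.flatnonzero(roc.thresholds == thr)[0]
        assert roc.tpr[chosen] == roc.tpr[ties].max()


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
        assert (
            m.sensitivity == m.specificity == m.ppv == m.npv == m.accuracy == 1.0
        )

    def test_published_count_arithmetic(self):
        # counts tp=164, fp=104, fn=36, tn=696 reconstructed as score/label
        # arrays; strict-threshold classification at 0.5
        scores = np.array([1.0] * (164 + 104) + [0.0] * (36 + 696))
        labels = np.array([1] * 164 + [0] * 104 + [1] * 36 + [0] * 696)
        m = confusion_metrics(scores, labels, 0.5)
        assert m.counts.tp == 164 and m.counts.fp == 104
        assert m.sensitivity == pytest.approx(0.82)
        assert m.specificity == pytest.approx(0.87)
        assert m.accuracy == pytest.approx(0.86)
        assert m.ppv == pytest.approx(164 / 268)  # ~0.612, the Bayes-consistent value
        assert m.npv == pytest.approx(696 / 732)  # ~0.951

    def test_threshold_above_max_score(self):
        m = confusion_metrics([0.2, 0.4, 0.6], [1, 0, 1], 0.9)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_undefined_ratios_are_absent_not_zero(self):
        m = confusion_metrics([0.2, 0.4], [0, 0], 0.9)
        assert m.sensitivity is None and m.auc is None
        assert m.ppv is None  # nothing classified positive
        assert m.specificity == 1.0

    def test_complement_identities(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        thr = float(np.median(scores))
        m = confusion_metrics(scores, labels, thr)
        fnr = m.counts.fn / (m.counts.fn + m.counts.tp)
        fpr = m.counts.fp / (m.counts.fp + m.counts.tn)
        assert m.sensitivity + fnr == pytest.approx(1.0)
        assert m.specificity + fpr == pytest.approx(1.0)


class TestBootstrap:
    def test_constant_statistic_gives_zero_width(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        lo, hi = bootstrap_ci(lambda s, y: 0.7, scores, labels, B=100, seed=0)
        assert lo == hi == 0.7

    def test_interval_contains_point_estimate_for_auc(self, injured_cohort):
        scores, labels = injured_cohort.scores(), injured_cohort.labels()
        lo, hi = bootstrap_ci(roc_auc, scores, labels, B=2000, seed=0)
        point = roc_auc(scores, labels)
        assert lo <= point <= hi
        assert 0.8 < lo < hi < 1.0

    def test_proportion_matches_binomial_percentiles(self):
        # stratified resampling of a {0,1} score: the case-stratum mean is a
        # binomial(n1, k/n1)/n1 draw with a closed-form percentile interval
        n1, k = 100, 37
        scores = np.array([1.0] * k + [0.0] * (n1 - k) + [0.5] * 100)
        labels = np.array([1] * n1 + [0] * 100)
        stat = lambda s, y: s[y == 1].mean()
        lo, hi = bootstrap_ci(stat, scores, labels, B=10_000, seed=1)
        exact_lo = stats.binom.ppf(0.025, n1, k / n1) / n1
        exact_hi = stats.binom.ppf(0.975, n1, k / n1) / n1
        assert lo == pytest.approx(exact_lo, abs=0.01)
        assert hi == pytest.approx(exact_hi, abs=0.01)

    def test_reproducible_from_seed(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        a = bootstrap_ci(roc_auc, scores, labels, B=200, seed=7)
        b = bootstrap_ci(roc_auc, scores, labels, B=200, seed=7)
        assert a == b


class TestDeLong:
    def test_identical_samples_give_z_zero(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        res = delong_test(scores, labels, scores, labels)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_antisymmetry(self, rng):
        s_a, s_b = rng.normal(size=30), rng.normal(size=30) + 0.5
        y_a = rng.integers(0, 2, size=30)
        y_b = rng.integers(0, 2, size=30)
        y_a[:2] = [0, 1]
        y_b[:2] = [0, 1]
        ab = delong_test(s_a, y_a, s_b, y_b)
        ba = delong_test(s_b, y_b, s_a, y_a)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p_value == pytest.approx(ba.p_value)
        assert 0.0 <= ab.p_value <= 1.0

    def test_variance_matches_direct_placement_computation(self):
        scores = np.array([3.1, 2.7, 1.4, 4.2, 0.9, 2.0, 3.6, 1.1])
        labels = np.array([1, 1, 0, 1, 0, 0, 1, 0])
        cases = scores[labels == 1]
        ctrls = scores[labels == 0]
        # explicit per-observation placement values
        v10 = np.array([np.mean([(c > d) + 0.5 * (c == d) for d in ctrls]) for c in cases])
        v01 = np.array([np.mean([(c > d) + 0.5 * (c == d) for c in cases]) for d in ctrls])
        var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(ctrls)
        other = np.array([0.2, 0.9, 0.4, 0.8, 0.1, 0.7, 0.3, 0.6])
        res = delong_test(scores, labels, other, labels)
        auc_b = roc_auc(other, labels)
        v10b = np.array(
            [np.mean([(c > d) + 0.5 * (c == d) for d in other[labels == 0]]) for c in other[labels == 1]]
        )
        v01b = np.array(
            [np.mean([(c > d) + 0.5 * (c == d) for c in other[labels == 1]]) for d in other[labels == 0]]
        )
        var_b = v10b.var(ddof=1) / 4 + v01b.var(ddof=1) / 4
        expected_z = (v10.mean() - auc_b) / np.sqrt(var + var_b)
        assert res.z == pytest.approx(expected_z, rel=1e-12)

    def test_degenerate_placements_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            delong_test([1, 1, 0, 0], [1, 1, 0, 0], [1, 1, 0, 0], [1, 1, 0, 0])


class TestHosmerLemeshow:
    def test_perfectly_calibrated_bins_give_zero(self):
        # ten bins, each with observed rate equal to its constant risk
        probs, outcomes = [], []
        for k in range(10):
            p = (k + 1) / 20.0  # 0.05 .. 0.50
            probs += [p] * 20
            outcomes += [1] * int(round(20 * p)) + [0] * (20 - int(round(20 * p)))
        table = hosmer_lemeshow(np.array(probs), np.array(outcomes), g=10)
        assert table.chi2 == pytest.approx(0.0, abs=1e-12)
        assert table.df == 8

    def test_half_and_half_at_single_probability(self):
        probs = np.full(20, 0.5)
        outcomes = np.array([1] * 10 + [0] * 10)
        table = hosmer_lemeshow(probs, outcomes, g=2)
        # all probabilities tie, so the bins collapse into one
        assert table.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_arithmetic(self):
        probs = np.array([0.2] * 10 + [0.8] * 10)
        outcomes = np.array([1] * 3 + [0] * 7 + [1] * 7 + [0] * 3)
        table = hosmer_lemeshow(probs, outcomes, g=2)
        # bin1: E1=2, O1=3 -> 1/2 + 1/8; bin2: E1=8, O1=7 -> 1/8 + 1/2
        assert table.chi2 == pytest.approx(0.5 + 0.125 + 0.125 + 0.5)
        assert len(table.bins) == 2

    def test_invariant_to_within_bin_ordering(self, rng):
        probs = rng.uniform(0.05, 0.95, size=200)
        outcomes = (rng.random(200) < probs).astype(int)
        t1 = hosmer_lemeshow(probs, outcomes, g=10)
        perm = rng.permutation(200)
        t2 = hosmer_lemeshow(probs[perm], outcomes[perm], g=10)
        assert t1.chi2 == pytest.approx(t2.chi2, rel=1e-12)
        assert t1.df == t2.df

    def test_bin_sizes_sum_to_total(self, rng):
        probs = rng.uniform(0, 1, size=137)
        outcomes = rng.integers(0, 2, size=137)
        table = hosmer_lemeshow(probs, outcomes, g=10)
        assert int(table.bins["n"].sum()) == 137

    def test_zero_expected_bins_are_merged(self):
        probs = np.array([0.0] * 10 + [0.5] * 10)
        outcomes = np.array([0] * 10 + [1] * 5 + [0] * 5)
        table = hosmer_lemeshow(probs, outcomes, g=2)
        assert table.merged_bins >= 1
        assert len(table.bins) == 1

    def test_matches_statsmodels_style_chi2(self, rng):
        # independent re-computation of the chi-square from the bin table
        probs = rng.uniform(0.1, 0.9, size=300)
        outcomes = (rng.random(300) < probs).astype(int)
        table = hosmer_lemeshow(probs, outcomes, g=10)
        chi2 = 0.0
        for _, row in table.bins.iterrows():
            chi2 += (row.o1 - row.e1) ** 2 / row.e1 + (row.o0 - row.e0) ** 2 / row.e0
        assert table.chi2 == pytest.approx(chi2)
        assert table.p_value == pytest.approx(
            float(stats.chi2.sf(chi2, table.df))
        )
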