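"""Metric suite, bootstrap CIs, DeLong/NRI/IDI comparison tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutriface.evaluation import (
    ConfusionCounts,
    EvaluationError,
    binary_metrics,
    bootstrap_ci,
    compare_models,
    confusion_from_predictions,
    delong_test,
    delong_variance,
    idi,
    micro_auc,
    nri,
)


class TestBinaryMetrics:
    def test_balanced_sensitivity(self):
        ms = binary_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=5))
        assert ms.sensitivity == 0.5

    def test_perfect_classifier(self):
        ms = binary_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
        assert (ms.accuracy, ms.sensitivity, ms.specificity, ms.ppv, ms.npv) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_fractions(self):
        ms = binary_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert ms.accuracy == pytest.approx(8 / 10)
        assert ms.sensitivity == pytest.approx(3 / 4)
        assert ms.specificity == pytest.approx(5 / 6)
        assert ms.ppv == pytest.approx(3 / 4)
        assert ms.npv == pytest.approx(5 / 6)

    def test_undefined_ratio_is_nan_not_zero(self):
        ms = binary_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert math.isnan(ms.ppv)
        assert ms.specificity == 1.0


class TestMicroAuc:
    def test_one_hot_perfect(self):
        y = np.array([0, 1, 2, 1])
        P = np.eye(3)[y]
        assert micro_auc(P, y) == 1.0

    def test_uniform_probabilities_exactly_half(self):
        y = np.array([0, 1, 2, 0, 2])
        P = np.full((5, 3), 1 / 3)
        assert micro_auc(P, y) == 0.5

    def test_matches_pairwise_counting_oracle(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 3, size=10)
        while np.unique(y).size < 2:
            y = rng.integers(0, 3, size=10)
        P = rng.dirichlet(np.ones(3), size=10)
        got = micro_auc(P, y)
        # pooled one-vs-rest pairs counted explicitly
        labels, scores = [], []
        for i in range(10):
            for k in range(3):
                labels.append(1 if y[i] == k else 0)
                scores.append(P[i, k])
        num, den = 0.0, 0
        for i, (li, si) in enumerate(zip(labels, scores)):
            for j, (lj, sj) in enumerate(zip(labels, scores)):
                if li == 1 and lj == 0:
                    den += 1
                    num += 1.0 if si > sj else (0.5 if si == sj else 0.0)
        assert got == pytest.approx(num / den, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 3, size=12)
        if np.unique(y).size < 2:
            return
        P = rng.dirichlet(np.ones(3), size=12)
        a = micro_auc(P, y)
        b = micro_auc(np.exp(3 * P), y)  # strictly monotone transform
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            micro_auc(np.full((4, 3), 1 / 3), np.zeros(4, dtype=int))


class TestBootstrap:
    def test_constant_data_zero_width(self):
        lo, hi = bootstrap_ci(np.mean, np.full(20, 3.5), B=200, seed=0)
        assert lo == hi == 3.5

    def test_same_seed_identical(self):
        x = np.random.default_rng(1).normal(size=50)
        assert bootstrap_ci(np.mean, x, B=300, seed=9) == bootstrap_ci(
            np.mean, x, B=300, seed=9)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (50, 200, 800):
            x = rng.normal(size=n)
            lo, hi = bootstrap_ci(np.mean, x, B=500, seed=3)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_b_too_small_rejected(self):
        with pytest.raises(EvaluationError):
            bootstrap_ci(np.mean, np.arange(10.0), B=50)


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 20)
        s = rng.normal(size=40)
        delta, p = delong_test(s, s, y)
        assert delta == 0.0 and p == 1.0

    def test_structural_components_hand_calculation(self):
        # n = 6: 3 events (scores 0.9, 0.8, 0.4), 3 nonevents (0.7, 0.3, 0.1)
        y = np.array([1, 1, 1, 0, 0, 0])
        a = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.1])
        b = np.array([0.6, 0.5, 0.2, 0.8, 0.4, 0.3])
        delta, p = delong_test(a, b, y)
        # explicit placement values: V10_i = mean_j psi(x_i, y_j)
        def components(s):
            x, yn = s[:3], s[3:]
            v10 = np.array([np.mean([(xi > yj) + 0.5 * (xi == yj) for yj in yn]) for xi in x])
            v01 = np.array([np.mean([(xi > yj) + 0.5 * (xi == yj) for xi in x]) for yj in yn])
            return v10.mean(), v10, v01

        auc_a, v10a, v01a = components(a)
        auc_b, v10b, v01b = components(b)
        assert delta == pytest.approx(auc_a - auc_b, abs=1e-12)
        var = (
            np.var(v10a - v10b, ddof=1) / 3 + np.var(v01a - v01b, ddof=1) / 3
        )
        from scipy import stats

        z = (auc_a - auc_b) / math.sqrt(var)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_zero_covariance_reduces_to_unpaired_sum(self):
        # independent scores: paired variance ~ sum of single-model variances
        rng = np.random.default_rng(6)
        y = np.array([0, 1] * 30)
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        va = delong_variance(a, y)
        vb = delong_variance(b, y)
        # recompute paired variance with the covariance term zeroed
        from nutriface.evaluation import _structural_components

        _, v10a, v01a = _structural_components(y, a)
        _, v10b, v01b = _structural_components(y, b)
        m, n = v10a.size, v01a.size
        var_nocov = (np.var(v10a, ddof=1) + np.var(v10b, ddof=1)) / m + (
            np.var(v01a, ddof=1) + np.var(v01b, ddof=1)) / n
        assert var_nocov == pytest.approx(va + vb, rel=1e-12)


class TestNri:
    def test_identical_classifications_zero(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        p = np.array([0.9, 0.8, 0.1, 0.2, 0.7, 0.3])
        value, pv = nri(p, p, y)
        assert value == 0.0

    def test_event_up_down_cancellation(self):
        # two events move in opposite directions; nonevents unchanged
        y = np.array([1, 1, 0, 0])
        old = np.array([0.2, 0.9, 0.2, 0.2])
        new = np.array([0.9, 0.2, 0.2, 0.2])
        value, _ = nri(old, new, y)
        assert value == 0.0

    def test_eight_subject_tabular_oracle(self):
        # 4 events: 2 up, 1 down, 1 same; 4 nonevents: 1 up, 2 down, 1 same
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        old = np.array([0.2, 0.2, 0.9, 0.5, 0.5, 0.9, 0.9, 0.2])
        new = np.array([0.9, 0.5, 0.5, 0.5, 0.9, 0.5, 0.2, 0.2])
        value, p = nri(old, new, y)
        expected = (2 / 4 - 1 / 4) + (2 / 4 - 1 / 4)  # four-proportion formula
        assert value == pytest.approx(expected, abs=1e-12)
        assert 0 <= p <= 1

    def test_no_events_rejected(self):
        with pytest.raises(EvaluationError):
            nri(np.array([0.1, 0.2]), np.array([0.2, 0.3]), np.array([0, 0]))


class TestIdi:
    def test_identical_probabilities_zero(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([0.8, 0.2, 0.7, 0.4])
        value, pv = idi(p, p, y)
        assert value == 0.0 and pv == 1.0

    def test_additive_shift_on_events_only(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        old = np.array([0.5, 0.6, 0.7, 0.2, 0.3, 0.4])
        new = old + np.where(y == 1, 0.1, 0.0)
        value, _ = idi(old, new, y)
        assert value == pytest.approx(0.1, abs=1e-12)

    def test_discrimination_slope_difference_oracle(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 6 + [0] * 6)
        old = rng.uniform(size=12)
        new = rng.uniform(size=12)
        value, _ = idi(old, new, y)
        slope_old = old[:6].mean() - old[6:].mean()
        slope_new = new[:6].mean() - new[6:].mean()
        assert value == pytest.approx(slope_new - slope_old, abs=1e-12)


class TestCompareModels:
    def test_all_three_tests_populated(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 3, size=60)
        Pa = rng.dirichlet(np.ones(3), size=60)
        Pb = rng.dirichlet(np.ones(3), size=60)
        res = compare_models(Pa, Pb, y)
        for p in (res.delong_p, res.nri_p, res.idi_p):
            assert 0 <= p <= 1
        assert math.isfinite(res.delta_auc)
        assert math.isfinite(res.nri) and math.isfinite(res.idi)


def test_confusion_from_predictions_counts():
    t = np.array([1, 1, 0, 0, 1])
    p = np.array([1, 0, 0, 1, 1])
    c = confusion_from_predictions(t, p)
    assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 1, 1)
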