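"""Evaluation: confusion metrics vs counting oracle, phi equivalence,
Rubin's rules, and split averaging."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossimpute import (EvalReport, average_over_splits, confusion_metrics,
                         correlation_bias, pool_mi_diagnostics, rubin_pool)


def brute_force_confusion(truth, pred):
    """Independent counting oracle: iterate the labeled pairs one by one."""
    tp = fp = fn = tn = 0
    for t, p in zip(truth, pred):
        if t and p:
            tp += 1
        elif not t and p:
            fp += 1
        elif t and not p:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def phi_from_table(x, y):
    """phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) from the 2x2 table."""
    a = sum(1 for i, j in zip(x, y) if i == 1 and j == 1)
    b = sum(1 for i, j in zip(x, y) if i == 1 and j == 0)
    c = sum(1 for i, j in zip(x, y) if i == 0 and j == 1)
    d = sum(1 for i, j in zip(x, y) if i == 0 and j == 0)
    den = math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return (a * d - b * c) / den


class TestConfusionMetrics:
    def test_worked_example(self):
        # tp=2 fp=1 fn=1 tn=6 over ten labeled pairs
        truth = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        pred = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        m = confusion_metrics(np.array(truth, bool), np.array(pred, bool))
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.specificity == pytest.approx(6 / 7)
        assert m.ppv == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.8)

    def test_perfect_classifier(self):
        v = np.array([1, 0, 1, 1, 0], bool)
        m = confusion_metrics(v, v)
        assert (m.sensitivity, m.specificity, m.ppv, m.accuracy) == (1, 1, 1, 1)

    def test_undefined_ppv_is_flagged_not_zero(self):
        truth = np.array([1, 1, 0], bool)
        pred = np.zeros(3, bool)
        m = confusion_metrics(truth, pred)
        assert m.sensitivity == 0.0
        assert math.isnan(m.ppv) and "ppv" in m.undefined

    def test_misaligned_series_rejected(self):
        a = pd.Series([1, 0], index=["x", "y"])
        b = pd.Series([1, 0], index=["y", "x"])
        with pytest.raises(ValueError, match="aligned"):
            confusion_metrics(a, b)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    def test_matches_counting_oracle(self, pairs):
        truth = np.array([t for t, _ in pairs], bool)
        pred = np.array([p for _, p in pairs], bool)
        tp, fp, fn, tn = brute_force_confusion(truth, pred)
        m = confusion_metrics(truth, pred)
        assert (m.counts.tp, m.counts.fp, m.counts.fn, m.counts.tn) == \
               (tp, fp, fn, tn)
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tp + fp:
            assert m.ppv == pytest.approx(tp / (tp + fp))
        assert m.accuracy == pytest.approx((tp + tn) / len(pairs))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_accuracy_decomposition_identity(self, seed):
        # accuracy == (sens*P + spec*N) / (P + N), and Bayes' identity for
        # ppv, on randomized instances with both classes present
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        truth = np.zeros(n, bool)
        truth[: max(1, n // 3)] = True
        rng.shuffle(truth)
        pred = rng.random(n) < 0.5
        m = confusion_metrics(truth, pred)
        P, N = truth.sum(), (~truth).sum()
        if not np.isnan(m.sensitivity) and not np.isnan(m.specificity):
            assert m.accuracy == pytest.approx(
                (m.sensitivity * P + m.specificity * N) / (P + N))
            prev = P / n
            denom = m.sensitivity * prev + (1 - m.specificity) * (1 - prev)
            if denom > 0:
                assert m.ppv == pytest.approx(m.sensitivity * prev / denom)


class TestCorrelationBias:
    def test_identical_vectors(self):
        v = np.array([1, 0, 1, 1, 0, 0])
        assert correlation_bias(v, v).r == pytest.approx(1.0)

    def test_complement_vectors(self):
        v = np.array([1, 0, 1, 1, 0, 0])
        assert correlation_bias(v, 1 - v).r == pytest.approx(-1.0)

    def test_hand_computed_phi(self):
        # 2x2 counts (30, 20 / 20, 30) -> phi = 0.2
        x = np.repeat([1, 1, 0, 0], [30, 20, 20, 30])
        y = np.repeat([1, 0, 1, 0], [30, 20, 20, 30])
        assert correlation_bias(x, y).r == pytest.approx(0.2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlation_bias(np.ones(5), np.array([1, 0, 1, 0, 1]))

    def test_ci_brackets_estimate(self):
        x = np.repeat([1, 1, 0, 0], [30, 20, 20, 30])
        y = np.repeat([1, 0, 1, 0], [30, 20, 20, 30])
        ci = correlation_bias(x, y)
        assert ci.lo < ci.r < ci.hi

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_pearson_equals_phi_on_binary(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 120))
        x = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
        y = (rng.random(n) < rng.uniform(0.2, 0.8)).astype(int)
        if x.min() == x.max() or y.min() == y.max():
            return
        assert correlation_bias(x, y).r == pytest.approx(phi_from_table(x, y))


class TestRubinPooling:
    def test_hand_worked_m3_example(self):
        # estimates 0.10, 0.20, 0.30; within variances 0.01 each
        # qbar = 0.20; W = 0.01; B = var([.1,.2,.3], ddof=1) = 0.01
        # T = 0.01 + (1 + 1/3) * 0.01 = 0.0233...
        pooled = rubin_pool([0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        assert pooled.estimate == pytest.approx(0.2)
        assert pooled.within == pytest.approx(0.01)
        assert pooled.between == pytest.approx(0.01)
        assert pooled.total_variance == pytest.approx(0.01 + (4 / 3) * 0.01)

    def test_pooled_estimate_is_mean_of_estimates(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=7)
        pooled = rubin_pool(q, np.full(7, 0.05))
        assert pooled.estimate == pytest.approx(q.mean())

    def test_zero_between_variance_collapses_to_single_ci(self):
        single = rubin_pool([0.4], [0.02])
        many = rubin_pool([0.4] * 5, [0.02] * 5)
        assert many.lo == pytest.approx(single.lo)
        assert many.hi == pytest.approx(single.hi)

    def test_between_variance_widens_interval(self):
        tight = rubin_pool([0.4] * 3, [0.02] * 3)
        spread = rubin_pool([0.2, 0.4, 0.6], [0.02] * 3)
        assert (spread.hi - spread.lo) > (tight.hi - tight.lo)

    def test_m1_is_single_stochastic_imputation(self):
        pooled = rubin_pool([0.3], [0.01])
        assert pooled.m == 1 and pooled.between == 0.0


class TestPoolMIDiagnostics:
    def test_identical_datasets_match_single_dataset_ci(self):
        rng = np.random.default_rng(3)
        status = (rng.random(200) < 0.4).astype(float)
        outcome = np.where(rng.random(200) < 0.3, status, rng.random(200) < 0.5)
        comp = pd.DataFrame({f"status_imp_{m}": status for m in range(1, 5)})
        pooled = pool_mi_diagnostics(comp, outcome)
        single = correlation_bias(status, outcome)
        assert pooled.estimate == pytest.approx(single.r)
        assert pooled.lo == pytest.approx(single.lo, abs=1e-9)
        assert pooled.hi == pytest.approx(single.hi, abs=1e-9)

    def test_between_variance_makes_interval_wider(self):
        rng = np.random.default_rng(4)
        outcome = (rng.random(300) < 0.5).astype(float)
        comp = pd.DataFrame({
            f"status_imp_{m}": (rng.random(300) < 0.4).astype(float)
            for m in range(1, 6)})
        pooled = pool_mi_diagnostics(comp, outcome)
        within_half = 1.96 * math.sqrt(pooled.within)
        assert (pooled.hi - pooled.lo) / 2 > within_half * 0.99
        assert pooled.between > 0


class TestAverageOverSplits:
    def test_singleton_is_identity(self):
        r = EvalReport(method="rf", per_split=[{"a": 0.5, "b": 1.0}])
        merged = average_over_splits([r])
        assert merged.averaged == {"a": 0.5, "b": 1.0}

    def test_arithmetic_mean(self):
        r1 = EvalReport(method="rf", per_split=[{"sens": 0.6}])
        r2 = EvalReport(method="rf", per_split=[{"sens": 0.8}])
        assert average_over_splits([r1, r2]).averaged["sens"] == \
               pytest.approx(0.7)

    def test_mean_matches_recomputation_from_parts(self):
        rng = np.random.default_rng(8)
        reports = [EvalReport(method="knn",
                              per_split=[{"x": float(v)} for v in
                                         rng.random(3)])
                   for _ in range(10)]
        merged = average_over_splits(reports)
        raw = [s["x"] for r in reports for s in r.per_split]
        assert merged.averaged["x"] == pytest.approx(np.mean(raw))

    def test_heterogeneous_metric_sets_rejected(self):
        r1 = EvalReport(method="rf", per_split=[{"a": 0.1}])
        r2 = EvalReport(method="rf", per_split=[{"b": 0.2}])
        with pytest.raises(ValueError, match="heterogeneous"):
            average_over_splits([r1, r2])

    def test_mixed_methods_rejected(self):
        r1 = EvalReport(method="rf", per_split=[{"a": 0.1}])
        r2 = EvalReport(method="knn", per_split=[{"a": 0.2}])
        with pytest.raises(ValueError, match="mix"):
            average_over_splits([r1, r2])
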