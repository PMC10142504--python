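"""Cohort validation statistics against independent oracles."""

from itertools import combinations

import numpy as np
import pytest

from pseudoprog.model import PSP, TP_MIXED
from pseudoprog.stats import (
    concordance_pearson,
    ks_normality_gate,
    loocv,
    mann_whitney,
    roc_auc,
)


def brute_force_auc(scores, labels, positive=TP_MIXED):
    """Concordant-pair fraction over all positive x negative pairs."""
    s = np.asarray(scores, float)
    pos = s[np.asarray(labels) == positive]
    neg = s[np.asarray(labels) != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def exact_mw_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = len(pooled)

    def u_stat(idx_a):
        aa = pooled[list(idx_a)]
        bb = pooled[[i for i in range(n) if i not in idx_a]]
        return sum((x > y) + 0.5 * (x == y) for x in aa for y in bb)

    u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
    us = np.array([u_stat(c) for c in combinations(range(n), len(a))])
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestKSGate:
    def test_gaussian_sample_passes(self):
        x = np.random.default_rng(1).normal(size=10_000)
        assert ks_normality_gate(x)["distribution"] == "gaussian"

    def test_exponential_sample_flagged(self):
        x = np.random.default_rng(1).exponential(size=10_000)
        assert ks_normality_gate(x)["distribution"] == "non_gaussian"

    def test_constant_sample_degenerate(self):
        out = ks_normality_gate(np.full(20, 3.0))
        assert out["degenerate"] and out["distribution"] == "non_gaussian"

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            ks_normality_gate([1.0, 2.0])


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 labelings as extreme

    def test_identical_groups(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n^2/2
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            na, nb = rng.integers(2, 5), rng.integers(2, 5)
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))  # tie-free
            a, b = pooled[:na], pooled[na:]
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(exact_mw_p(a, b), abs=1e-10)

    def test_power_at_one_sigma_shift(self):
        """Delta = 1 sigma, n=37 vs 19: rejection rate above 0.85."""
        rng = np.random.default_rng(99)
        reject = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(1.0, 1.0, 37)
            b = rng.normal(0.0, 1.0, 19)
            _, p = mann_whitney(a, b)
            reject += p < 0.05
        assert reject / reps > 0.85

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestConcordancePearson:
    def test_perfect_agreement(self):
        truth = [PSP, TP_MIXED, PSP, TP_MIXED]
        r, _ = concordance_pearson([0.0, 1.0, 0.0, 1.0], truth)
        assert r == pytest.approx(1.0)

    def test_null_simulation_mean_near_zero(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(1000):
            pp = rng.uniform(size=56)
            truth = np.array([TP_MIXED] * 37 + [PSP] * 19)
            rs.append(concordance_pearson(pp, truth)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_printed_pp_distributions_give_r_in_band(self):
        """PP drawn from the published group PP stats (61.3+-39.1 vs
        15.1+-22.2, truncated to [0,100]) yields mean r in [0.4, 0.7],
        consistent with the published r = 0.56."""
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(1000):
            tp = np.clip(rng.normal(61.3, 39.1, 37), 0, 100)
            psp = np.clip(rng.normal(15.1, 22.2, 19), 0, 100)
            pp = np.concatenate([tp, psp]) / 100.0
            truth = np.array([TP_MIXED] * 37 + [PSP] * 19)
            rs.append(concordance_pearson(pp, truth)[0])
        assert 0.4 <= np.mean(rs) <= 0.7

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            concordance_pearson([0.5, 0.5, 0.5], [PSP, TP_MIXED, PSP])


class TestROC:
    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.1, 0.2], [TP_MIXED, TP_MIXED, PSP, PSP])
        assert r.auc == 1.0

    def test_all_ties_gives_half(self):
        r = roc_auc([0.5] * 6, [TP_MIXED] * 3 + [PSP] * 3)
        assert r.auc == 0.5

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.uniform(size=20)
        labels = rng.choice([PSP, TP_MIXED], 20)
        if len(set(labels)) < 2:
            labels[0], labels[1] = PSP, TP_MIXED
        r = roc_auc(scores, labels)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_matches_pairwise_oracle_small_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 11))
            scores = rng.choice(np.linspace(0, 1, 6), n)  # deliberate ties
            labels = np.array([TP_MIXED, PSP] * n)[:n]
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_complement_and_monotone_transform_invariance(self, rng):
        scores = rng.permutation(np.arange(12.0))  # tie-free
        labels = np.array([TP_MIXED, PSP] * 6)
        auc = roc_auc(scores, labels).auc
        assert auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)
        assert roc_auc(np.exp(scores / 3), labels).auc == pytest.approx(auc)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [PSP, PSP])


class TestLOOCV:
    def _separable_cohort(self, rng, n=20):
        half = n // 2
        X = np.column_stack(
            [
                np.r_[rng.normal(0.3, 0.005, half), rng.normal(0.05, 0.005, half)],
                rng.normal(0.05, 0.002, n),
                np.r_[rng.normal(8, 0.2, half), rng.normal(1, 0.2, half)],
            ]
        )
        y = np.array([TP_MIXED] * half + [PSP] * half)
        return X, y

    def test_wide_margin_separable_cohort_perfect(self, rng):
        X, y = self._separable_cohort(rng)
        assert loocv(X, y, refit=True).accuracy == 1.0

    def test_permuted_labels_near_majority_rate(self):
        """Null: LOOCV accuracy close to the majority-class rate."""
        rng = np.random.default_rng(31)
        accs = []
        for _ in range(30):
            X = np.column_stack(
                [
                    rng.normal(0.12, 0.03, 56),
                    rng.normal(0.045, 0.02, 56),
                    rng.normal(3.0, 1.5, 56),
                ]
            )
            y = rng.permutation(np.array([TP_MIXED] * 37 + [PSP] * 19))
            accs.append(loocv(X, y, refit=True).accuracy)
        assert abs(np.mean(accs) - 37 / 56) < 0.07

    def test_no_refit_equals_fixed_coefficient_concordance(self, rng):
        from pseudoprog.model import ProgressionClassifier, summarize_cohort

        X = np.column_stack(
            [rng.uniform(0.05, 0.2, 24), rng.uniform(0.01, 0.1, 24), rng.uniform(1, 8, 24)]
        )
        y = rng.choice([PSP, TP_MIXED], 24)
        res = loocv(X, y, refit=False)
        clf = ProgressionClassifier().fit(X, y)
        s = summarize_cohort(clf.predict(X), y)
        assert res.accuracy == pytest.approx(s.concordance_pct / 100.0)

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError):
            loocv(np.zeros((5, 3)), np.array([PSP] * 5))
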