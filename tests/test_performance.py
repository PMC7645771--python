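import numpy as np
import pytest
from scipy import stats

from faimsvoc.performance import (
    auc_inference,
    mann_whitney_auc,
    operating_point,
    predictive_values,
    reconstruct_confusion,
    roc_auc,
    round_half_up,
)


def brute_force_auc(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    return sum((p > q) + 0.5 * (p == q) for p in pos for q in neg) / (
        pos.size * neg.size
    )


def brute_force_youden(scores, labels):
    """Best J over every possible 'score >= t' threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    best = -np.inf
    best_sens = -1.0
    for t in np.r_[np.unique(s), np.inf]:
        pred = s >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1
        if j > best + 1e-12 or (abs(j - best) <= 1e-12 and sens > best_sens):
            best, best_sens = j, sens
    return best, best_sens


class TestRocAuc:
    def test_separable(self):
        _, auc = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        assert auc == 1.0

    def test_half_concordant(self):
        _, auc = roc_auc([0.9, 0.3, 0.8, 0.4], [1, 1, 0, 0])
        assert auc == 0.5

    def test_all_ties(self):
        _, auc = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_auc_matches_brute_force_pair_counting(self, rng):
        """1000 random instances, 1e-12 agreement with pair counting, and
        the trapezoidal curve integral equals the concordance."""
        for _ in range(1000):
            n = rng.integers(4, 20)
            s = np.round(rng.normal(size=n), rng.integers(0, 3))  # force ties often
            y = np.zeros(n, dtype=bool)
            y[: rng.integers(1, n - 1)] = True
            y = rng.permutation(y)
            if y.all() or not y.any():
                continue
            curve, auc = roc_auc(s, y)
            assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            assert np.trapezoid(curve.tpr, curve.fpr) == pytest.approx(auc, abs=1e-12)

    def test_curve_monotone_and_anchored(self, rng):
        s, y = rng.normal(size=25), rng.integers(0, 2, 25).astype(bool)
        y[0], y[1] = True, False
        curve, _ = roc_auc(s, y)
        assert curve.fpr[0] == 0 and curve.tpr[0] == 0
        assert curve.fpr[-1] == 1 and curve.tpr[-1] == 1
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_negation_and_monotone_invariance(self, rng):
        s, y = rng.normal(size=30), rng.integers(0, 2, 30).astype(bool)
        y[0], y[1] = True, False
        auc = mann_whitney_auc(s, y)
        assert mann_whitney_auc(-s, y) == pytest.approx(1 - auc, abs=1e-12)
        assert mann_whitney_auc(np.exp(s), y) == pytest.approx(auc, abs=1e-12)


class TestOperatingPoint:
    def test_separable_perfect_point(self):
        curve, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
        _, sens, spec = operating_point(curve)
        assert (sens, spec) == (1.0, 1.0)

    def test_all_ties_j_zero(self):
        curve, _ = roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        _, sens, spec = operating_point(curve)
        assert sens + spec - 1 == pytest.approx(0.0)
        assert sens == 1.0  # tie resolved towards sensitivity

    def test_matches_exhaustive_threshold_scan(self, rng):
        for _ in range(200):
            n = rng.integers(6, 25)
            s = np.round(rng.normal(size=n), 1)
            y = np.zeros(n, dtype=bool)
            y[: rng.integers(2, n - 1)] = True
            y = rng.permutation(y)
            if y.all() or not y.any():
                continue
            curve, _ = roc_auc(s, y)
            _, sens, spec = operating_point(curve)
            best_j, best_sens = brute_force_youden(s, y)
            assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)
            assert sens == pytest.approx(best_sens, abs=1e-12)


class TestPredictiveValues:
    def test_mortality_row(self):
        """Published mortality row: sens 29/38, spec 12/19 at 38/19 ->
        PPV prints 0.81, NPV prints 0.57."""
        ppv, npv = predictive_values(29 / 38, 12 / 19, 38, 19)
        assert round_half_up(ppv) == 0.81
        assert round_half_up(npv) == 0.57

    def test_validation_row(self):
        """SAM-vs-controls: sens 55/57, spec 7/7 -> NPV 7/9 prints 0.78."""
        ppv, npv = predictive_values(55 / 57, 1.0, 57, 7)
        assert npv == pytest.approx(7 / 9)
        assert round_half_up(npv) == 0.78
        assert ppv == 1.0

    def test_perfect(self):
        assert predictive_values(1.0, 1.0, 10, 5) == (1.0, 1.0)

    def test_degenerate_flagged(self):
        ppv, _ = predictive_values(0.0, 1.0, 5, 5)
        assert np.isnan(ppv)


class TestReconstructConfusion:
    def test_mortality_row_unique(self):
        cands = reconstruct_confusion(0.76, 0.63, 38, 19)
        assert len(cands) == 1
        c = cands[0]
        assert (c.positive_arm, c.tp, c.tn) == ("a", 29, 12)

    def test_perfect_rates_collapse_orientations(self):
        cands = reconstruct_confusion(1.00, 1.00, 10, 5)
        tps = {(c.tp, c.tn) for c in cands}
        assert (10, 5) in tps

    def test_early_mortality_row(self):
        """Early-mortality row (0.89, 0.55) with arms 9/38: death-positive
        orientation gives TP 8 of 9, TN 21 of 38 (PPV 0.32, NPV 0.95)."""
        cands = [
            c
            for c in reconstruct_confusion(0.89, 0.55, 9, 38)
            if c.positive_arm == "a"
        ]
        assert len(cands) == 1
        c = cands[0]
        assert (c.tp, c.tn) == (8, 21)
        ppv, npv = predictive_values(c.tp / 9, c.tn / 38, 9, 38)
        assert round_half_up(ppv) == 0.32
        assert round_half_up(npv) == 0.95

    def test_inconsistent_rates_report_empty(self):
        assert reconstruct_confusion(0.33, 0.5, 2, 2) == []


class TestAucInference:
    def test_perfect_separation_small_p(self):
        rng = np.random.default_rng(0)
        s = np.r_[rng.uniform(0.6, 1.0, 20), rng.uniform(0.0, 0.4, 20)]
        y = np.r_[np.ones(20), np.zeros(20)].astype(bool)
        (lo, hi), p = auc_inference(s, y, n_boot=200, n_perm=2000, seed=1)
        assert p <= 0.001
        assert lo == hi == 1.0

    def test_all_tied_ci_contains_half(self):
        s = np.full(20, 0.3)
        y = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        (lo, hi), _ = auc_inference(s, y, n_boot=200, n_perm=500, seed=1)
        assert lo <= 0.5 <= hi

    def test_delong_ci_brackets_auc(self, rng):
        s, y = rng.normal(size=40), np.r_[np.ones(20), np.zeros(20)].astype(bool)
        s[y] += 1.0
        (lo, hi), _ = auc_inference(s, y, ci_method="delong", n_perm=200, seed=0)
        auc = mann_whitney_auc(s, y)
        assert lo <= auc <= hi

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            auc_inference([0.1, 0.5, 0.9], [1, 0, 0], seed=0)
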