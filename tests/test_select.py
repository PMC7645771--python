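from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from faimsvoc.layout import Geometry
from faimsvoc.select import (
    feature_map_coordinates,
    rank_sum_feature_scores,
    top_k_features,
)


def brute_force_u(a, b):
    """Concordant-pair count (+ half ties): the definition of U."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def exact_p_oracle(a, b):
    """Exact two-sided p by enumerating every C(n, n1) label assignment."""
    values = np.concatenate([a, b])
    n1 = len(a)
    n = values.size
    ranks = stats.rankdata(values)
    us = np.array(
        [ranks[list(c)].sum() - n1 * (n1 + 1) / 2 for c in combinations(range(n), n1)]
    )
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestRankSumOracles:
    def test_textbook_example_exact(self):
        """A={1,2,3} vs B={4,5,6}: U=0 and exact two-sided p = 2/20."""
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        r = rank_sum_feature_scores(X, [1, 1, 1, 0, 0, 0])
        assert r.u_statistic[0] == 0
        assert r.p_value[0] == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 5), (4, 4), (8, 8), (8, 3)])
    def test_u_matches_brute_force_pair_count(self, n1, n2, rng):
        for _ in range(20):
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            X = np.concatenate([a, b])[:, None]
            y = np.r_[np.ones(n1), np.zeros(n2)]
            r = rank_sum_feature_scores(X, y)
            assert r.u_statistic[0] == pytest.approx(brute_force_u(a, b))

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (8, 7)])
    def test_exact_p_matches_enumeration(self, n1, n2, rng):
        for _ in range(10):
            a, b = rng.normal(size=n1), rng.normal(size=n2)
            X = np.concatenate([a, b])[:, None]
            y = np.r_[np.ones(n1), np.zeros(n2)]
            r = rank_sum_feature_scores(X, y)
            assert r.p_value[0] == pytest.approx(exact_p_oracle(a, b))

    def test_asymptotic_matches_scipy(self, rng):
        """Beyond the exact regime the tie-corrected normal approximation
        must agree with the reference implementation."""
        a, b = rng.normal(size=15), rng.normal(size=12)
        X = np.concatenate([a, b])[:, None]
        y = np.r_[np.ones(15), np.zeros(12)]
        r = rank_sum_feature_scores(X, y)
        ref = stats.mannwhitneyu(a, b, method="asymptotic")
        assert r.u_statistic[0] == pytest.approx(ref.statistic)
        assert r.p_value[0] == pytest.approx(ref.pvalue)

    def test_constant_feature_p1_ranked_last(self, rng):
        X = np.column_stack([rng.normal(size=8), np.full(8, 3.0)])
        y = np.r_[np.ones(4), np.zeros(4)]
        r = rank_sum_feature_scores(X, y)
        assert r.p_value[1] == 1.0
        assert r.order[-1] == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two non-empty classes"):
            rank_sum_feature_scores(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_null_p_values_uniform(self):
        """Permuting labels makes p-values uniform (KS, alpha=0.01).

        Tested in the asymptotic regime (15 vs 15), where the p-value
        support is dense enough for a continuous-uniform KS reference; the
        small-sample exact p is discrete and covered by the enumeration
        oracle above."""
        rng = np.random.default_rng(777)
        x = rng.normal(size=30)[:, None]
        ps = []
        base = np.r_[np.ones(15), np.zeros(15)].astype(bool)
        for _ in range(400):
            ps.append(rank_sum_feature_scores(x, rng.permutation(base)).p_value[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSelectionProperties:
    def test_invariant_under_monotone_transform(self, rng):
        X = rng.normal(size=(14, 30))
        y = rng.integers(0, 2, 14)
        y[:2], y[-2:] = 1, 0
        r1 = rank_sum_feature_scores(X, y)
        r2 = rank_sum_feature_scores(np.exp(X / 3.0) + 5, y)
        assert np.array_equal(top_k_features(r1, 10), top_k_features(r2, 10))

    def test_tie_broken_by_flat_index(self, rng):
        col = rng.normal(size=10)
        X = np.column_stack([col, col])  # identical features -> identical p
        y = np.r_[np.ones(5), np.zeros(5)]
        r = rank_sum_feature_scores(X, y)
        assert list(top_k_features(r, 2)) == [0, 1]

    def test_k_exceeding_retained_warns_and_returns_all(self, rng):
        X = rng.normal(size=(8, 5))
        y = np.r_[np.ones(4), np.zeros(4)]
        r = rank_sum_feature_scores(X, y)
        with pytest.warns(UserWarning, match="exceeds"):
            sel = top_k_features(r, 50)
        assert sorted(sel) == list(range(5))

    def test_planted_signal_recovered(self, rng):
        """Effect d=2 at known features: most of the top-k is planted."""
        n1, n2, p = 20, 20, 500
        planted = rng.choice(p, 40, replace=False)
        X = rng.normal(size=(n1 + n2, p))
        X[:n1, planted] += 2.0
        y = np.r_[np.ones(n1), np.zeros(n2)]
        sel = top_k_features(rank_sum_feature_scores(X, y), 40)
        frac = np.isin(sel, planted).mean()
        assert frac >= 0.5


class TestFeatureMapCoordinates:
    def test_layout_corners(self):
        geom = Geometry(51, 512)
        coords = feature_map_coordinates(np.array([0, 52223]), geom)
        first, last = coords.iloc[0], coords.iloc[1]
        assert (first["polarity"], first["df_percent"], first["cv_volts"]) == (
            "positive", 0.0, 6.0,
        )
        assert (last["polarity"], last["df_percent"], last["cv_volts"]) == (
            "negative", 100.0, -6.0,
        )

    def test_round_trip_bijection(self, rng):
        from faimsvoc.layout import flat_index

        geom = Geometry(51, 512)
        idx = rng.choice(geom.n_features, 200, replace=False)
        coords = feature_map_coordinates(idx, geom)
        df_axis, cv_axis = geom.default_df_axis(), geom.default_cv_axis()
        rebuilt = [
            flat_index(
                row["polarity"],
                int(np.argmin(np.abs(df_axis - row["df_percent"]))),
                int(np.argmin(np.abs(cv_axis - row["cv_volts"]))),
                geom,
            )
            for _, row in coords.iterrows()
        ]
        assert np.array_equal(rebuilt, idx)

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            feature_map_coordinates(np.array([52224]), Geometry(51, 512))
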