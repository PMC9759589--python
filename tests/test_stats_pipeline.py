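"""Statistical pipeline: thresholds, group tests, correlations, selection."""

import math

import numpy as np
import pandas as pd
import pytest

from tsiplan import (
    assign_volume_group,
    bonferroni_threshold,
    chi_square,
    drop_multicollinear,
    kruskal_dunn,
    lasso_select,
    remove_multivariate_outliers,
    spearman_matrix,
    spearman_pair,
    univariate_regression,
)


class TestVolumeGroups:
    @pytest.mark.parametrize(
        "tv,group",
        [(0.5, 1), (0.999, 1), (1.0, 2), (3.0, 2), (5.0, 2), (5.001, 3), (20.01, 3)],
    )
    def test_grouping_rule(self, tv, group):
        assert assign_volume_group(tv) == group

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            assign_volume_group(0.0)


class TestBonferroni:
    def test_correlation_family(self):
        assert bonferroni_threshold(0.05, 40) == 0.00125

    def test_single_comparison(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_kruskal_family_matches_truncated_threshold(self):
        # 0.05/12 = 0.0041666...; printed threshold 0.0041 under truncation
        t = bonferroni_threshold(0.05, 12)
        assert math.floor(t * 1e4) / 1e4 == 0.0041

    def test_product_recovers_alpha(self):
        for m in (1, 12, 40):
            assert bonferroni_threshold(0.05, m) * m == pytest.approx(0.05)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestKruskalDunn:
    def test_all_equal(self):
        res = kruskal_dunn(np.ones(30), np.repeat([1, 2, 3], 10))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert not res.significant

    def test_shifted_groups_all_pairs_significant(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(0, 1, 50), rng.normal(5, 1, 50), rng.normal(10, 1, 50)]
        )
        groups = np.repeat([1, 2, 3], 50)
        res = kruskal_dunn(values, groups)
        assert res.significant
        assert all(res.dunn_significant.values())

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_dunn(np.arange(10.0), np.ones(10))


class TestChiSquare:
    def test_balanced_table(self):
        stat, p = chi_square([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # expected counts all 20; sum (O-E)^2/E = 4 * 100/20 = 20
        table = np.array([[30, 10], [10, 30]], float)
        expected = np.array([[20.0, 20.0], [20.0, 20.0]])
        by_hand = float(((table - expected) ** 2 / expected).sum())
        stat, p = chi_square(table)
        assert stat == pytest.approx(by_hand) == pytest.approx(20.0)
        assert p < 0.001

    def test_zero_expected_raises(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])


class TestOutlierElimination:
    def test_clean_data_removal_bounded(self):
        rng = np.random.default_rng(0)
        keep = remove_multivariate_outliers(rng.normal(size=(200, 2)))
        assert (~keep).mean() <= 0.08

    def test_planted_outliers_removed(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(size=(200, 2)), 10.0 * np.ones((5, 2))])
        keep = remove_multivariate_outliers(X)
        assert not keep[-5:].any()

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError):
            remove_multivariate_outliers(np.eye(3))


class TestSpearman:
    def test_strictly_increasing_pair(self):
        x = np.linspace(0, 1, 30)
        r, p, n_used, n_removed = spearman_pair(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 0.00125
        assert n_used + n_removed == 30

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        r1, *_ = spearman_pair(x, x, eliminate_outliers=False)
        r2, *_ = spearman_pair(x, np.exp(x), eliminate_outliers=False)
        assert r1 == pytest.approx(r2) == pytest.approx(1.0)

    def test_normal_copula_closed_form(self):
        """Spearman r of a bivariate normal: (6/pi) arcsin(rho/2)."""
        rho = 0.6
        expected = 6.0 / math.pi * math.asin(rho / 2.0)
        rng = np.random.default_rng(3)
        cov = [[1.0, rho], [rho, 1.0]]
        rs = []
        for _ in range(300):
            xy = rng.multivariate_normal([0, 0], cov, size=234)
            r, *_ = spearman_pair(xy[:, 0], xy[:, 1], eliminate_outliers=False)
            rs.append(r)
        assert np.mean(rs) == pytest.approx(expected, abs=0.03)

    def test_matrix_layout_and_significance(self, small_cohort):
        results = spearman_matrix(small_cohort)
        assert len(results) == 8 * 5
        for res in results:
            assert -1.0 <= res.r <= 1.0 or math.isnan(res.r)
            assert res.n_used + res.n_outliers_removed == len(small_cohort)
            assert res.significant == (res.p < 0.00125 if math.isfinite(res.p) else False)


class TestMulticollinearity:
    def test_constructed_collinear_pair(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": -x + 1e-8 * rng.normal(size=100),
                           "z": rng.normal(size=100)})
        kept = drop_multicollinear(df, ["x", "y", "z"])
        assert "z" in kept
        assert len(kept) == 2

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        assert drop_multicollinear(df, list("abcd")) == list("abcd")

    def test_exact_monotone_pair_drops_one(self, small_cohort):
        kept = drop_multicollinear(
            small_cohort, ["sphericity", "spherical_disproportion"]
        )
        assert len(kept) == 1


class TestLassoSelect:
    def _planted_table(self, n=234, seed=0):
        rng = np.random.default_rng(seed)
        cols = ["vios", "f1", "f2", "f3", "f4", "f5"]
        df = pd.DataFrame(rng.normal(size=(n, 6)), columns=cols)
        df["resp"] = df["vios"] + rng.normal(0, 0.1 * df["vios"].std(), n)
        return df, cols

    def test_planted_signal_recovered(self):
        df, cols = self._planted_table()
        sel = lasso_select(df, cols, "resp", repeats=20, seed=1)
        assert sel.top_feature == "vios"
        top_per_repeat = sel.coefficients.abs().idxmax(axis=1)
        assert (top_per_repeat == "vios").mean() >= 0.95

    def test_pure_noise_coefficients_small(self):
        rng = np.random.default_rng(6)
        cols = list("abcdef")
        df = pd.DataFrame(rng.normal(size=(234, 6)), columns=cols)
        df["resp"] = rng.normal(size=234)
        sel = lasso_select(df, cols, "resp", repeats=20, seed=2)
        assert sel.mean_abs_coef.max() < 0.1

    def test_reproducible(self):
        df, cols = self._planted_table()
        s1 = lasso_select(df, cols, "resp", repeats=5, seed=3)
        s2 = lasso_select(df, cols, "resp", repeats=5, seed=3)
        assert s1.coefficients.equals(s2.coefficients)

    def test_constant_response_raises(self):
        df, cols = self._planted_table()
        df["flat"] = 1.0
        with pytest.raises(ValueError):
            lasso_select(df, cols, "flat")


class TestUnivariateRegression:
    def test_exact_line(self):
        res = univariate_regression([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.adjusted_r_squared == pytest.approx(1.0)

    def test_null_mean_adjusted_r2_near_zero(self):
        rng = np.random.default_rng(7)
        adj = [
            univariate_regression(rng.normal(size=234), rng.normal(size=234)).adjusted_r_squared
            for _ in range(400)
        ]
        assert np.mean(adj) == pytest.approx(0.0, abs=0.01)

    def test_population_r2_recovered(self):
        """Simulated pairs with population R^2 = 0.33 fit near that value."""
        rng = np.random.default_rng(8)
        target_r2 = 0.33
        beta = math.sqrt(target_r2 / (1 - target_r2))
        fits = []
        for _ in range(50):
            x = rng.normal(size=234)
            y = beta * x + rng.normal(size=234)
            fits.append(univariate_regression(x, y).adjusted_r_squared)
        assert abs(np.mean(fits) - target_r2) < 0.08

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            univariate_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
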