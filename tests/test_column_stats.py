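import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccgcolumn.column_stats import (
    binned_relationship,
    class_composition_tests,
    distance_match,
    fit_exponential_decay,
    fit_linear,
    fit_standardized_regression,
    layer_logistic_regression,
    one_proportion_ztest,
    simple_complex_direction_test,
)


class TestBinnedRelationship:
    def test_constant_y(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, 200)
        out = binned_relationship(x, np.full(200, 7.0))
        assert (out["stat"] == 7.0).all()
        assert ((out["ci_hi"] - out["ci_lo"]) == 0).all()

    def test_identity_monotone(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 500)
        out = binned_relationship(x, x, stat="mean")
        assert (np.diff(out["stat"]) > 0).all()

    def test_median_stat(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 100)
        out = binned_relationship(x, x**2, stat="median", n_bins=5)
        assert len(out) == 5

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            binned_relationship(np.arange(5), np.arange(5), n_bins=10)

    def test_tied_edges_merged(self):
        x = np.r_[np.zeros(50), np.random.default_rng(0).uniform(1, 2, 50)]
        out = binned_relationship(x, x, n_bins=10)
        assert len(out) <= 10  # merged, no crash


class TestFitLinear:
    def test_noiseless_slope_recovered_exactly(self):
        x = np.linspace(0, 1000, 50)
        y = 0.0026 * x + 1.0  # 1.3 ms per 500 um
        slope, intercept, r = fit_linear(x, y)
        assert slope == pytest.approx(0.0026, abs=1e-12)
        assert intercept == pytest.approx(1.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_constant_y_zero_slope(self):
        slope, _, _ = fit_linear(np.arange(10.0), np.full(10, 3.0))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_mae_robust_to_outlier(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 50)
        y = 2 * x + rng.normal(0, 0.01, 50)
        y[10] += 500.0
        s_mse, *_ = fit_linear(x, y, cost="MSE")
        s_mae, *_ = fit_linear(x, y, cost="MAE")
        assert abs(s_mae - 2.0) < abs(s_mse - 2.0)

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_linear(np.ones(5), np.arange(5.0))


class TestFitExponential:
    def test_noiseless_half_distance_recovered(self):
        x = np.linspace(0, 600, 30)
        y = 0.04 * 2 ** (-x / 154.0)
        a, lam, half, _ = fit_exponential_decay(x, y)
        assert half == pytest.approx(154.0, rel=1e-3)
        assert a == pytest.approx(0.04, rel=1e-3)

    def test_constant_y_flags_no_decay(self):
        _, lam, half, _ = fit_exponential_decay(np.linspace(0, 100, 10), np.full(10, 2.0))
        assert np.isinf(lam) and np.isinf(half)

    def test_nonpositive_y_raises(self):
        with pytest.raises(ValueError, match="positive"):
            fit_exponential_decay(np.arange(5.0), np.array([1, 2, 0, 1, 1.0]))

    def test_noisy_recovery_within_15pct(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 500, 400)
        y = 0.04 * np.exp(-x / (150.0 / np.log(2))) * np.exp(rng.normal(0, 0.1, 400))
        # fit on binned medians, as in the analysis
        med = binned_relationship(x, y, stat="median", seed=0)
        _, _, half, _ = fit_exponential_decay(
            med["bin_center"].to_numpy(), med["stat"].to_numpy()
        )
        assert half == pytest.approx(150.0, rel=0.15)


class TestDistanceMatch:
    def _pairs(self, distances, lags=None, effs=None, roris=None):
        n = len(distances)
        return pd.DataFrame(
            dict(
                distance_um=distances,
                peak_lag_ms=lags if lags is not None else np.zeros(n),
                peak_efficacy=effs if effs is not None else np.zeros(n),
                r_ori=roris if roris is not None else np.zeros(n),
            )
        )

    def test_adjacent_pairing_drops_leftover(self):
        out = distance_match(self._pairs([10, 12, 50, 53, 100.0]))
        assert out["n_matches"] == 2
        np.testing.assert_allclose(sorted(out["matched"]["d_distance"]), [2.0, 3.0])

    def test_identical_distances_zero_delta(self):
        out = distance_match(self._pairs(np.full(10, 5.0)))
        assert (out["matched"]["d_distance"] == 0).all()

    def test_tuning_effect_signs(self):
        # efficacy rises and |lag| falls with r_ori, independent of distance
        rng = np.random.default_rng(5)
        n = 2000
        d = np.sort(rng.uniform(0, 500, n))
        r = rng.uniform(-0.5, 1.0, n)
        lag = 5 - 3 * r + rng.normal(0, 0.5, n)
        eff = 0.02 + 0.02 * r + rng.normal(0, 0.002, n)
        out = distance_match(self._pairs(d, lag, eff, r))
        assert out["corr_defficacy_drori"] > 0
        assert out["corr_dlag_drori"] < 0

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            distance_match(self._pairs([1.0]))


class TestStandardizedRegression:
    def _make(self, n, noise_sd, seed=0):
        rng = np.random.default_rng(seed)
        zd = rng.normal(size=n)
        zr = rng.normal(size=n)
        lag = 2.48 + 0.94 * zd - 0.37 * zr + rng.normal(0, noise_sd, n)
        return pd.DataFrame(
            dict(
                peak_lag_ms=lag,
                peak_efficacy=np.zeros(n),
                distance_um=zd * 80 + 200,  # affine-rescaled raw predictors
                r_ori=zr * 0.3 + 0.25,
            )
        )

    def test_noiseless_exact(self):
        # predictors standardized in-sample, large intercept keeps lag > 0
        rng = np.random.default_rng(0)
        zd = rng.uniform(-2, 2, 200)
        zr = rng.uniform(-2, 2, 200)
        zd = (zd - zd.mean()) / zd.std()
        zr = (zr - zr.mean()) / zr.std()
        df = pd.DataFrame(
            dict(
                peak_lag_ms=10.0 + 0.94 * zd - 0.37 * zr,
                peak_efficacy=np.zeros(200),
                distance_um=zd,
                r_ori=zr,
            )
        )
        res = fit_standardized_regression(df, "peak_lag", remove_outliers=False)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.coefficients[0] == pytest.approx(0.94, abs=1e-6)
        assert res.coefficients[1] == pytest.approx(-0.37, abs=1e-6)
        assert res.intercept == pytest.approx(10.0, abs=1e-6)

    def test_affine_invariance_of_coefficients(self):
        df = self._make(500, 0.5, seed=2)
        r1 = fit_standardized_regression(df, "peak_lag")
        df2 = df.copy()
        df2["distance_um"] = df2["distance_um"] * 13 + 7
        r2 = fit_standardized_regression(df2, "peak_lag")
        np.testing.assert_allclose(r1.coefficients, r2.coefficients, atol=1e-9)

    def test_outlier_removal_restores_recovery(self):
        df = self._make(3000, 0.3, seed=3)
        df.loc[:20, "peak_lag_ms"] = 500.0  # gross outliers
        res = fit_standardized_regression(df, "peak_lag", remove_outliers=True)
        assert res.coefficients[0] == pytest.approx(0.94, abs=0.08)
        res_no = fit_standardized_regression(df, "peak_lag", remove_outliers=False)
        assert abs(res_no.coefficients[0] - 0.94) > abs(res.coefficients[0] - 0.94)

    def test_collinear_predictors_raise(self):
        df = self._make(100, 0.1)
        df["r_ori"] = df["distance_um"] * 2
        with pytest.raises(ValueError, match="collinear"):
            fit_standardized_regression(df, "peak_lag")

    def test_too_few_pairs_raise(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_standardized_regression(self._make(5, 0.1), "peak_lag")


class TestCompositionTests:
    def _pairs(self, labels, within, distances=None, roris=None):
        n = len(labels)
        return pd.DataFrame(
            dict(
                ref_unit=np.arange(n),
                target_unit=np.arange(n) + 1000,
                class_label=labels,
                layer_ref=["5"] * n,
                layer_target=np.where(within, "5", "2/3"),
                distance_um=distances if distances is not None else np.zeros(n),
                r_ori=roris if roris is not None else np.zeros(n),
            )
        )

    def test_balanced_table_chi2_zero(self):
        labels = ["S_sync"] * 100 + ["F_async"] * 100
        within = [True] * 50 + [False] * 50 + [True] * 50 + [False] * 50
        out = class_composition_tests(self._pairs(labels, np.array(within)))
        assert out["chi_squared"]["chi2"] == pytest.approx(0.0)
        assert out["chi_squared"]["p"] == pytest.approx(1.0)

    def test_half_proportion_z_zero(self):
        z, p = one_proportion_ztest(50, 100)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_z_30_of_40(self):
        z, p = one_proportion_ztest(30, 40)
        assert z == pytest.approx((0.75 - 0.5) / np.sqrt(0.25 / 40), abs=1e-9)
        assert z == pytest.approx(3.162, abs=0.01)
        assert p < 0.05

    def test_planted_within_between_pattern(self):
        rng = np.random.default_rng(6)
        labels, within = [], []
        for _ in range(300):
            if rng.random() < 0.5:
                labels.append(rng.choice(["S_sync", "B_sync"]))
                within.append(rng.random() < 0.8)
            else:
                labels.append(rng.choice(["F_async", "R_async"]))
                within.append(rng.random() < 0.2)
        out = class_composition_tests(self._pairs(labels, np.array(within)))
        wb = out["within_between"].set_index("class_label")
        assert wb.loc["S_sync", "within_proportion"] > 0.5
        assert wb.loc["F_async", "within_proportion"] < 0.5
        assert wb.loc["S_sync", "p_bonferroni"] < 0.05
        assert wb.loc["F_async", "p_bonferroni"] < 0.05

    def test_rank_sum_distance_differences(self):
        rng = np.random.default_rng(7)
        labels = ["S_sync"] * 100 + ["F_async"] * 100
        within = np.array([True] * 200)
        d = np.r_[rng.normal(100, 10, 100), rng.normal(300, 10, 100)]
        out = class_composition_tests(self._pairs(labels, within, distances=d))
        rs = out["rank_sums"]
        row = rs[(rs.metric == "distance_um")].iloc[0]
        assert row["p_bonferroni"] < 0.01


class TestLayerLogistic:
    def _pairs(self, n, rule=None, seed=0):
        rng = np.random.default_rng(seed)
        d = rng.uniform(90, 300, n)
        same = rng.random(n) < 0.5
        if rule == "same_layer_bsync":
            p = np.where(same, 0.7, 0.2)
            labels = np.where(rng.random(n) < p, "B_sync", "S_sync")
        else:
            labels = rng.choice(["B_sync", "S_sync"], n)
        return pd.DataFrame(
            dict(
                class_label=labels,
                distance_um=d,
                layer_ref=np.where(same, "5", "5"),
                layer_target=np.where(same, "5", "6"),
            )
        )

    def test_null_coefficients_near_zero(self):
        hits = 0
        for seed in range(20):
            out = layer_logistic_regression(self._pairs(400, seed=seed), "B_sync")
            coef = out.set_index("predictor")
            ok = all(
                abs(coef.loc[p, "coefficient"]) <= 2.5 * coef.loc[p, "std_error"]
                for p in ("distance", "same_layer")
            )
            hits += ok
        assert hits >= 17

    def test_planted_same_layer_effect(self):
        out = layer_logistic_regression(
            self._pairs(600, rule="same_layer_bsync", seed=1), "B_sync"
        )
        coef = out.set_index("predictor")
        assert coef.loc["same_layer", "coefficient"] > 0
        assert coef.loc["same_layer", "p_value"] < 0.01

    def test_empty_distance_range_raises(self):
        with pytest.raises(ValueError, match="distance range"):
            layer_logistic_regression(self._pairs(100), "B_sync", distance_range=(1e6, 2e6))


class TestSimpleComplexDirection:
    def test_planted_forward_dominance(self):
        n = 60
        pairs = pd.DataFrame(
            dict(
                ref_unit=np.arange(n),
                target_unit=np.arange(n) + 1000,
                class_label=["F_async"] * 45 + ["R_async"] * 15,
            )
        )
        cell_class = pd.Series(
            {**{i: "simple" for i in range(n)}, **{i + 1000: "complex" for i in range(n)}}
        )
        out = simple_complex_direction_test(pairs, cell_class)
        assert out["forward_proportion"] > 0.5
        assert out["p"] < 0.05

    def test_no_simple_complex_pairs(self):
        pairs = pd.DataFrame(
            dict(ref_unit=[0], target_unit=[1], class_label=["F_async"])
        )
        cell_class = pd.Series({0: "complex", 1: "complex"})
        out = simple_complex_direction_test(pairs, cell_class)
        assert out["n_pairs"] == 0
        assert np.isnan(out["z"])

    def test_null_proportion_near_half(self):
        rng = np.random.default_rng(8)
        n = 400
        labels = rng.choice(["F_async", "R_async"], n)
        pairs = pd.DataFrame(
            dict(ref_unit=np.arange(n), target_unit=np.arange(n) + 1000,
                 class_label=labels)
        )
        cell_class = pd.Series(
            {**{i: "simple" for i in range(n)}, **{i + 1000: "complex" for i in range(n)}}
        )
        out = simple_complex_direction_test(pairs, cell_class)
        assert abs(out["forward_proportion"] - 0.5) < 3 * np.sqrt(0.25 / n)
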