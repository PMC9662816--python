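import numpy as np
import pandas as pd
import pytest

from ccgcolumn.correlogram import (
    CcgCurve,
    JitterConfig,
    ccg_from_arrays,
    compute_all_pairs,
    corrected_ccg,
    detect_peak,
    expected_jitter_rates,
    jitter_expected_ccg,
    raw_ccg,
    sample_jittered,
    screen_double_counts,
)
from ccgcolumn.data_model import BinnedSpikes


def random_binned(seed, n_units=2, m=10, n=300, p=0.03):
    rng = np.random.default_rng(seed)
    x = (rng.random((n_units, m, n)) < p).astype(np.uint8)
    return BinnedSpikes(
        window=(0.0, n * 1e-3),
        bin_width_s=0.001,
        unit_ids=np.arange(n_units),
        trial_ids=np.arange(m),
        x=x,
    )


class TestRawCcg:
    def test_hand_fixture_matches_equation(self, hand_binned):
        c = raw_ccg(hand_binned, 0, 1, max_lag_ms=5)
        at = lambda lag: c.raw[np.flatnonzero(c.lags_ms == lag)[0]]  # noqa: E731
        assert at(1) == pytest.approx(1.2)
        assert at(-1) == pytest.approx(0.6)
        assert c.theta[np.flatnonzero(c.lags_ms == 0)[0]] == 6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mirror_symmetry_bit_exact(self, seed):
        b = random_binned(seed)
        fwd = raw_ccg(b, 0, 1)
        rev = raw_ccg(b, 1, 0)
        assert np.array_equal(fwd.raw[::-1], rev.raw)
        assert np.array_equal(fwd.mirrored().raw, rev.raw)

    def test_theta_symmetric_and_peaks_at_zero(self):
        b = random_binned(3)
        c = raw_ccg(b, 0, 1)
        assert np.array_equal(c.theta, c.theta[::-1])
        assert c.theta[np.flatnonzero(c.lags_ms == 0)[0]] == b.n_bins

    def test_zero_rate_unit_raises(self):
        b = random_binned(0)
        b.x[1] = 0
        b.lambda_per_bin = b.x.mean(axis=(1, 2))
        with pytest.raises(ValueError, match="positive rate"):
            raw_ccg(b, 0, 1)

    def test_independent_poisson_flank_level(self):
        # E[CCG(tau)] = sqrt(lambda_j lambda_k) at every lag for independent trains
        b = random_binned(11, m=180, n=600, p=0.02)
        c = raw_ccg(b, 0, 1)
        expected = float(np.sqrt(b.lambda_per_bin[0] * b.lambda_per_bin[1]))
        se = c.raw.std() / np.sqrt(len(c.raw))
        assert abs(c.raw.mean() - expected) < 4 * se


class TestJitter:
    def test_flat_psth_gives_uniform_expected_rate(self):
        # 25 trials, one spike per trial at distinct bins of a 25-bin window:
        # PSTH is flat, each trial count 1 -> expected rate 1/25 everywhere
        m, w = 25, 25
        x = np.zeros((m, w), np.uint8)
        x[np.arange(m), np.arange(w)] = 1
        r = expected_jitter_rates(x, w)
        np.testing.assert_allclose(r, 1.0 / 25)

    def test_expected_rates_preserve_trial_counts(self):
        rng = np.random.default_rng(5)
        x = (rng.random((20, 100)) < 0.05).astype(np.uint8)
        r = expected_jitter_rates(x, 25)
        win_counts = x.reshape(20, 4, 25).sum(axis=2)
        np.testing.assert_allclose(r.reshape(20, 4, 25).sum(axis=2), win_counts)

    def test_monte_carlo_draw_preserves_counts(self):
        rng = np.random.default_rng(6)
        x = (rng.random((20, 100)) < 0.05).astype(np.uint8)
        s = sample_jittered(x, 25, rng)
        np.testing.assert_array_equal(
            s.reshape(20, 4, 25).sum(axis=2), x.reshape(20, 4, 25).sum(axis=2)
        )

    def test_window_must_tile(self):
        b = random_binned(0, n=300)
        with pytest.raises(ValueError, match="whole number|tile"):
            jitter_expected_ccg(b, 0, 1, JitterConfig(window_ms=7))

    def test_analytic_matches_monte_carlo(self):
        # oracle: the closed form equals the mean over seeded jitter draws
        b = random_binned(21, m=20, n=200, p=0.04)
        max_lag = 50
        analytic = jitter_expected_ccg(b, 0, 1, JitterConfig(25), max_lag_ms=max_lag)
        rng = np.random.default_rng(99)
        lam0, lam1 = b.lambda_per_bin
        draws = []
        for _ in range(400):
            a = sample_jittered(b.x[0], 25, rng)
            c = sample_jittered(b.x[1], 25, rng)
            draws.append(ccg_from_arrays(a, c, lam0, lam1, max_lag))
        draws = np.asarray(draws)
        se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws)) + 1e-12
        assert np.all(np.abs(draws.mean(axis=0) - analytic.jittered) < 4 * se)

    def test_monte_carlo_mode_runs(self):
        b = random_binned(2, m=5, n=100)
        mc = jitter_expected_ccg(
            b, 0, 1, JitterConfig(25, mode="monte_carlo", n_resamples=20, seed=0),
            max_lag_ms=20,
        )
        assert mc.jittered.shape == (41,)

    def test_stimulus_locked_pair_corrected_to_zero(self):
        # identical strong stimulus locking, independent trains otherwise
        rng = np.random.default_rng(42)
        m, n = 100, 200
        profile = 0.01 + 0.15 * np.exp(-np.arange(n) / 30.0)  # onset transient
        x = (rng.random((2, m, n)) < profile).astype(np.uint8)
        b = BinnedSpikes((0, n * 1e-3), 0.001, np.arange(2), np.arange(m), x)
        raw = raw_ccg(b, 0, 1, max_lag_ms=50)
        jit = jitter_expected_ccg(b, 0, 1, JitterConfig(25), max_lag_ms=50)
        corr = corrected_ccg(raw, jit)
        # raw CCG is strongly inflated near zero; correction removes it
        flank = np.sqrt(b.lambda_per_bin.prod())
        assert raw.raw.max() > 1.5 * flank
        assert np.abs(corr.corrected.mean()) < 0.1 * flank


class TestCorrected:
    def test_jittered_equals_raw_gives_zero(self, hand_binned):
        c = raw_ccg(hand_binned, 0, 1, max_lag_ms=5)
        j = CcgCurve(0, 1, lags_ms=c.lags_ms, jittered=c.raw.copy())
        out = corrected_ccg(c, j)
        np.testing.assert_array_equal(out.corrected, np.zeros_like(c.raw))

    def test_axis_mismatch_raises(self, hand_binned):
        c = raw_ccg(hand_binned, 0, 1, max_lag_ms=5)
        j = CcgCurve(0, 1, lags_ms=c.lags_ms[:-1], jittered=c.raw[:-1].copy())
        with pytest.raises(ValueError, match="lag axes"):
            corrected_ccg(c, j)


def curve_with(peak_lag, z, lags=None, width_sd=1.0, noise_sd=0.001, seed=0):
    lags = np.arange(-100, 101) if lags is None else lags
    rng = np.random.default_rng(seed)
    noise = rng.normal(0, noise_sd, len(lags))
    bumpv = z * noise_sd * np.exp(-0.5 * ((lags - peak_lag) / width_sd) ** 2)
    return CcgCurve(0, 1, lags_ms=lags.astype(float), corrected=noise + bumpv)


class TestDetectPeak:
    def test_significant_peak_at_3ms(self):
        pf = detect_peak(curve_with(3, z=12))
        assert pf.significant
        assert pf.peak_lag_ms == 3

    def test_peak_beyond_10ms_not_significant(self):
        pf = detect_peak(curve_with(12, z=20))
        # the max within +-10 ms is just the bump tail; central z is small
        assert not pf.significant or abs(pf.peak_lag_ms) <= 10

    def test_zero_lag_peak(self):
        lags = np.arange(-100, 101).astype(float)
        c = np.zeros(len(lags))
        c[lags == 0] = 1.0
        pf = detect_peak(CcgCurve(0, 1, lags_ms=lags, corrected=c))
        assert pf.peak_lag_ms == 0
        assert pf.peak_efficacy == 1.0

    def test_tie_breaks_toward_small_abs_then_negative(self):
        lags = np.arange(-100, 101).astype(float)
        c = np.zeros(len(lags))
        c[lags == 5] = 1.0
        c[lags == -5] = 1.0
        pf = detect_peak(CcgCurve(0, 1, lags_ms=lags, corrected=c))
        assert pf.peak_lag_ms == -5

    def test_trough_is_sign_flipped_peak(self):
        cur = curve_with(4, z=15, seed=3)
        neg = CcgCurve(0, 1, lags_ms=cur.lags_ms, corrected=-cur.corrected)
        pf, nf = detect_peak(cur), detect_peak(neg)
        assert nf.z_trough == pytest.approx(-pf.z_peak)
        assert nf.trough_lag_ms == pf.peak_lag_ms
        assert nf.significant_trough == pf.significant

    def test_flat_curve_flagged(self):
        lags = np.arange(-100, 101).astype(float)
        pf = detect_peak(CcgCurve(0, 1, lags_ms=lags, corrected=np.zeros(len(lags))))
        assert pf.flagged and not pf.significant

    def test_noise_window_has_102_bins(self):
        lags = np.arange(-100, 101)
        flank = (np.abs(lags) >= 50) & (np.abs(lags) <= 100)
        assert flank.sum() == 102


class TestDoubleCounts:
    def _units(self, depths):
        return pd.DataFrame(
            dict(unit_id=np.arange(len(depths)), depth_um=depths,
                 layer=["5"] * len(depths))
        )

    def test_duplicated_unit_flagged(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 1, 200))
        spikes = pd.DataFrame(
            dict(unit_id=np.r_[np.zeros(200, int), np.ones(200, int)],
                 trial_id=0, time_s=np.r_[t, t])
        )
        out = screen_double_counts(spikes, self._units([0.0, 10.0]))
        assert out["flagged"].iloc[0]
        assert out["overlap_frac"].iloc[0] == 1.0

    def test_distant_pair_exempt(self):
        spikes = pd.DataFrame(
            dict(unit_id=[0, 1], trial_id=[0, 0], time_s=[0.5, 0.5])
        )
        out = screen_double_counts(spikes, self._units([0.0, 60.0]))
        assert len(out) == 0  # beyond 50 um: never evaluated

    def test_independent_pairs_rarely_flagged(self):
        rng = np.random.default_rng(1)
        rows = []
        for pair in range(30):
            for u in (2 * pair, 2 * pair + 1):
                t = rng.uniform(0, 1, 20)
                rows.append(pd.DataFrame(dict(unit_id=u, trial_id=0, time_s=t)))
        spikes = pd.concat(rows, ignore_index=True)
        depths = np.repeat(np.arange(30) * 1000.0, 2) + np.tile([0.0, 20.0], 30)
        out = screen_double_counts(spikes, self._units(depths))
        assert out["flagged"].sum() == 0


class TestComputeAllPairs:
    def test_pair_count_and_mirror(self):
        b = random_binned(7, n_units=5, m=8, n=300)
        units = pd.DataFrame(
            dict(unit_id=np.arange(5), depth_um=np.arange(5) * 100.0,
                 layer=["5"] * 5)
        )
        cs = compute_all_pairs(b, units, keep_all_curves=True)
        assert len(cs.pairs) == 10
        c01 = cs.curve(0, 1)
        c10 = cs.curve(1, 0)
        assert np.array_equal(c01[::-1], c10)
        assert (cs.pairs["distance_um"] >= 0).all()

    def test_flagged_pairs_excluded_from_significant(self):
        b = random_binned(8, n_units=2, m=8, n=300)
        units = pd.DataFrame(dict(unit_id=[0, 1], depth_um=[0.0, 10.0], layer=["5", "5"]))
        flags = pd.DataFrame(
            [dict(unit_a=0, unit_b=1, distance_um=10.0, overlap_frac=0.5, flagged=True)]
        )
        cs = compute_all_pairs(b, units, double_count_flags=flags)
        assert cs.pairs["double_count_flag"].iloc[0]
        assert cs.pairs["excluded"].iloc[0]
        assert len(cs.significant) == 0
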