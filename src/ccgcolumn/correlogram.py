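"""Raw, jitter-expected and corrected cross-correlograms, significance and peaks.

The correlogram between units *j* (reference) and *k* (target) at lag τ is

    CCG_{j-k}(τ) = (1/M) Σ_i Σ_t x_ji(t) · x_ki(t+τ) / (θ(τ) · sqrt(λ_j λ_k))

with M trials, N bins per trial, binary per-bin indicators x, per-bin mean
rates λ (spikes/bin) and the triangular overlap correction θ(τ) = N − |τ|.
Positive lags mean the reference unit leads.  Cross-trial products are never
formed; lag correlations are computed per trial via FFT.

The jitter null preserves each trial's spike count inside fixed jitter
windows and the across-trial PSTH.  Its expected correlogram has a closed
form: replace each spike train by its expected jittered rate

    r_ji(t) = n_ji(w(t)) · PSTH_j(t) / Σ_{t'∈w(t)} PSTH_j(t')

and evaluate the same correlogram formula on the two rate arrays (independent
jitters factorise).  A Monte-Carlo resampling mode is kept as a test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .data_model import BinnedSpikes

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG_MS = 100
PEAK_LAG_WINDOW_MS = 10
NOISE_FLANK_MS = (50, 100)
SIGNIFICANCE_SD = 7.0


@dataclass
class JitterConfig:
    """Configuration of the interval-jitter null."""

    window_ms: float = 25.0
    mode: str = "analytic"  # or "monte_carlo"
    n_resamples: int = 1000
    seed: int | None = None

    def window_bins(self, bin_width_s: float) -> int:
        w = self.window_ms * 1e-3 / bin_width_s
        if abs(w - round(w)) > 1e-9:
            raise ValueError("jitter window must be a whole number of bins")
        return int(round(w))


@dataclass
class CcgCurve:
    """Lag-indexed correlogram for one ordered unit pair."""

    reference_unit: int
    target_unit: int
    lags_ms: np.ndarray
    raw: np.ndarray | None = None
    jittered: np.ndarray | None = None
    corrected: np.ndarray | None = None
    theta: np.ndarray | None = None

    def mirrored(self) -> "CcgCurve":
        """The same pair with reference and target swapped: curves lag-reversed."""
        rev = lambda a: None if a is None else a[::-1].copy()  # noqa: E731
        return CcgCurve(
            reference_unit=self.target_unit,
            target_unit=self.reference_unit,
            lags_ms=self.lags_ms,
            raw=rev(self.raw),
            jittered=rev(self.jittered),
            corrected=rev(self.corrected),
            theta=None if self.theta is None else self.theta.copy(),
        )


@dataclass
class PeakFeatures:
    """Peak/trough summary of a corrected correlogram."""

    peak_lag_ms: float
    peak_efficacy: float
    noise_mean: float
    noise_sd: float
    z_peak: float
    significant: bool
    trough_lag_ms: float
    trough_value: float
    z_trough: float
    significant_trough: bool
    flagged: bool = False


def _lag_axis(max_lag: int) -> np.ndarray:
    return np.arange(-max_lag, max_lag + 1)


def _cross_counts(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray:
    """Σ_i Σ_t a_i(t)·b_i(t+τ) for τ = −max_lag … +max_lag.

    ``a``, ``b`` have shape (M, N); the sum runs within trials only.
    """
    m, n = a.shape
    nfft = sp_fft.next_fast_len(n + max_lag + 1)
    fa = sp_fft.rfft(a, n=nfft, axis=1)
    fb = sp_fft.rfft(b, n=nfft, axis=1)
    spec = np.einsum("mf,mf->f", np.conj(fa), fb)
    cc = sp_fft.irfft(spec, n=nfft)
    out = np.empty(2 * max_lag + 1)
    out[max_lag:] = cc[: max_lag + 1]
    out[:max_lag] = cc[nfft - max_lag :]
    # coincidence counts of integral inputs are integers; rounding removes FFT
    # noise and makes the j-k / k-j mirror identity exact
    if (a == np.rint(a)).all() and (b == np.rint(b)).all():
        out = np.rint(out)
    return out


def ccg_from_arrays(
    a: np.ndarray,
    b: np.ndarray,
    lam_a: float,
    lam_b: float,
    max_lag: int,
) -> np.ndarray:
    """Normalized correlogram of two (M, N) rate/indicator arrays."""
    if lam_a <= 0 or lam_b <= 0:
        raise ValueError("both units must have positive rate")
    m, n = a.shape
    counts = _cross_counts(a.astype(float), b.astype(float), max_lag)
    theta = n - np.abs(_lag_axis(max_lag))
    return counts / (m * theta * np.sqrt(lam_a * lam_b))


def raw_ccg(
    binned: BinnedSpikes, j: int, k: int, max_lag_ms: int = DEFAULT_MAX_LAG_MS
) -> CcgCurve:
    """Raw (uncorrected) correlogram between units ``j`` (reference) and ``k``."""
    ij, ik = binned.index_of(j), binned.index_of(k)
    lam_j = binned.lambda_per_bin[ij]
    lam_k = binned.lambda_per_bin[ik]
    max_lag = _bins_for_ms(max_lag_ms, binned.bin_width_s)
    curve = ccg_from_arrays(binned.x[ij], binned.x[ik], lam_j, lam_k, max_lag)
    lags = _lag_axis(max_lag) * binned.bin_width_s * 1e3
    theta = binned.n_bins - np.abs(_lag_axis(max_lag))
    return CcgCurve(j, k, lags_ms=lags, raw=curve, theta=theta.astype(float))


def _bins_for_ms(ms: float, bin_width_s: float) -> int:
    return int(round(ms * 1e-3 / bin_width_s))


def expected_jitter_rates(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Expected per-bin rate of a train under the interval-jitter null.

    ``x`` has shape (M, N); N must be a multiple of ``window_bins``.  Within
    each jitter window, each trial's spike count is redistributed over bins in
    proportion to the across-trial PSTH; a window with positive count but zero
    PSTH mass (unreachable with consistent data) falls back to uniform.
    """
    m, n = x.shape
    if n % window_bins:
        raise ValueError("jitter window does not tile the analysis window")
    n_win = n // window_bins
    xw = x.reshape(m, n_win, window_bins).astype(float)
    counts = xw.sum(axis=2)  # (M, n_win)
    psth_w = xw.mean(axis=0)  # (n_win, window_bins)
    mass = psth_w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(mass > 0, psth_w / mass, 1.0 / window_bins)
    r = counts[:, :, None] * profile[None, :, :]
    return r.reshape(m, n)


def sample_jittered(x: np.ndarray, window_bins: int, rng: np.random.Generator) -> np.ndarray:
    """One Monte-Carlo draw from the jitter null (counts, not clipped binary)."""
    m, n = x.shape
    if n % window_bins:
        raise ValueError("jitter window does not tile the analysis window")
    n_win = n // window_bins
    xw = x.reshape(m, n_win, window_bins)
    counts = xw.sum(axis=2).astype(np.int64)
    psth_w = xw.mean(axis=0).astype(float)
    out = np.zeros((m, n_win, window_bins))
    for w in range(n_win):
        mass = psth_w[w].sum()
        p = psth_w[w] / mass if mass > 0 else np.full(window_bins, 1.0 / window_bins)
        out[:, w, :] = rng.multinomial(counts[:, w], p)
    return out.reshape(m, n)


def jitter_expected_ccg(
    binned: BinnedSpikes,
    j: int,
    k: int,
    jitter: JitterConfig | None = None,
    max_lag_ms: int = DEFAULT_MAX_LAG_MS,
) -> CcgCurve:
    """Expected correlogram under the jitter null (analytic or Monte-Carlo)."""
    jitter = jitter or JitterConfig()
    ij, ik = binned.index_of(j), binned.index_of(k)
    lam_j = binned.lambda_per_bin[ij]
    lam_k = binned.lambda_per_bin[ik]
    max_lag = _bins_for_ms(max_lag_ms, binned.bin_width_s)
    wbins = jitter.window_bins(binned.bin_width_s)
    if jitter.mode == "analytic":
        rj = expected_jitter_rates(binned.x[ij], wbins)
        rk = expected_jitter_rates(binned.x[ik], wbins)
        curve = ccg_from_arrays(rj, rk, lam_j, lam_k, max_lag)
    elif jitter.mode == "monte_carlo":
        rng = np.random.default_rng(jitter.seed)
        acc = np.zeros(2 * max_lag + 1)
        for _ in range(jitter.n_resamples):
            aj = sample_jittered(binned.x[ij], wbins, rng)
            ak = sample_jittered(binned.x[ik], wbins, rng)
            acc += ccg_from_arrays(aj, ak, lam_j, lam_k, max_lag)
        curve = acc / jitter.n_resamples
    else:
        raise ValueError(f"unknown jitter mode {jitter.mode!r}")
    lags = _lag_axis(max_lag) * binned.bin_width_s * 1e3
    return CcgCurve(j, k, lags_ms=lags, jittered=curve)


def corrected_ccg(raw_curve: CcgCurve, jittered_curve: CcgCurve) -> CcgCurve:
    """Elementwise subtraction raw − jittered on identical lag axes."""
    if not np.array_equal(raw_curve.lags_ms, jittered_curve.lags_ms):
        raise ValueError("lag axes differ")
    return CcgCurve(
        reference_unit=raw_curve.reference_unit,
        target_unit=raw_curve.target_unit,
        lags_ms=raw_curve.lags_ms,
        raw=raw_curve.raw,
        jittered=jittered_curve.jittered,
        corrected=raw_curve.raw - jittered_curve.jittered,
        theta=raw_curve.theta,
    )


def _extremum_lag(values: np.ndarray, lags: np.ndarray, take_max: bool) -> int:
    """Index of the extremum; ties go to smaller |lag|, then negative lag."""
    target = values.max() if take_max else values.min()
    tied = np.flatnonzero(values == target)
    order = np.lexsort((lags[tied], np.abs(lags[tied])))
    return int(tied[order[0]])


def detect_peak(
    curve: CcgCurve,
    peak_window_ms: float = PEAK_LAG_WINDOW_MS,
    noise_flank_ms: tuple[float, float] = NOISE_FLANK_MS,
    threshold_sd: float = SIGNIFICANCE_SD,
) -> PeakFeatures:
    """Locate the corrected-CCG peak/trough and assess significance.

    The peak is the maximum of the corrected curve within ``peak_window_ms``
    of zero; noise statistics come from the corrected curve's flanks
    (``noise_flank_ms[0] ≤ |τ| ≤ noise_flank_ms[1]``).  Significance requires
    z = (peak − noise mean)/noise SD above ``threshold_sd``.  Trough features
    are computed symmetrically.
    """
    if curve.corrected is None:
        raise ValueError("corrected curve not populated")
    lags = curve.lags_ms
    c = curve.corrected
    central = np.abs(lags) <= peak_window_ms + 1e-9
    flank = (np.abs(lags) >= noise_flank_ms[0] - 1e-9) & (
        np.abs(lags) <= noise_flank_ms[1] + 1e-9
    )
    noise_mean = float(c[flank].mean())
    noise_sd = float(c[flank].std(ddof=0))

    cl, ll = c[central], lags[central]
    ip = _extremum_lag(cl, ll, take_max=True)
    it = _extremum_lag(cl, ll, take_max=False)
    peak, trough = float(cl[ip]), float(cl[it])

    flagged = noise_sd <= 0
    if flagged:
        z_peak = z_trough = np.nan
        sig = sig_trough = False
    else:
        z_peak = (peak - noise_mean) / noise_sd
        z_trough = (trough - noise_mean) / noise_sd
        sig = z_peak > threshold_sd
        sig_trough = z_trough < -threshold_sd

    return PeakFeatures(
        peak_lag_ms=float(ll[ip]),
        peak_efficacy=peak,
        noise_mean=noise_mean,
        noise_sd=noise_sd,
        z_peak=float(z_peak),
        significant=bool(sig),
        trough_lag_ms=float(ll[it]),
        trough_value=trough,
        z_trough=float(z_trough),
        significant_trough=bool(sig_trough),
        flagged=flagged,
    )


def screen_double_counts(
    spikes: pd.DataFrame,
    units: pd.DataFrame,
    dist_um: float = 50.0,
    coincidence_ms: float = 0.167,
    frac: float = 0.20,
) -> pd.DataFrame:
    """Flag unit pairs likely to share double-counted spikes.

    For pairs of units closer than ``dist_um`` along the probe, compute the
    fraction of the smaller train's spikes with a partner spike of the other
    unit within ``coincidence_ms`` in the same trial; flag pairs exceeding
    ``frac``.  Returns a DataFrame (unit_a, unit_b, distance_um, overlap_frac,
    flagged); pairs at or beyond ``dist_um`` are exempt and omitted.
    """
    depths = units.set_index("unit_id")["depth_um"]
    ids = units["unit_id"].to_numpy()
    tol = coincidence_ms * 1e-3
    by_unit = {
        u: g.sort_values(["trial_id", "time_s"]) for u, g in spikes.groupby("unit_id")
    }
    rows = []
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = int(ids[a_i]), int(ids[b_i])
            d = abs(depths[a] - depths[b])
            if d >= dist_um:
                continue
            sa = by_unit.get(a)
            sb = by_unit.get(b)
            if sa is None or sb is None or len(sa) == 0 or len(sb) == 0:
                overlap = 0.0
            else:
                small, big = (sa, sb) if len(sa) <= len(sb) else (sb, sa)
                big_by_trial = {t: g["time_s"].to_numpy() for t, g in big.groupby("trial_id")}
                n_match = 0
                for t, g in small.groupby("trial_id"):
                    bt = big_by_trial.get(t)
                    if bt is None:
                        continue
                    ts = g["time_s"].to_numpy()
                    pos = np.searchsorted(bt, ts)
                    left = np.abs(ts - bt[np.clip(pos - 1, 0, len(bt) - 1)])
                    right = np.abs(ts - bt[np.clip(pos, 0, len(bt) - 1)])
                    n_match += int((np.minimum(left, right) <= tol).sum())
                overlap = n_match / len(small)
            rows.append((a, b, float(d), overlap, overlap > frac))
    return pd.DataFrame(
        rows, columns=["unit_a", "unit_b", "distance_um", "overlap_frac", "flagged"]
    )


@dataclass
class CcgSet:
    """Correlogram features for every unordered pair plus stored curves.

    ``pairs`` holds one row per unordered pair with the reference-first
    ordering (ref_unit, target_unit); the mirrored ordering is implied by the
    exact symmetry CCG_{j-k}(τ) = CCG_{k-j}(−τ).  ``curves`` maps
    (ref, target) to the corrected curve for significant pairs.
    """

    pairs: pd.DataFrame
    lags_ms: np.ndarray
    curves: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def curve(self, ref: int, target: int) -> np.ndarray:
        if (ref, target) in self.curves:
            return self.curves[(ref, target)]
        if (target, ref) in self.curves:
            return self.curves[(target, ref)][::-1]
        raise KeyError((ref, target))

    @property
    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["significant"] & ~self.pairs["excluded"]]


def compute_all_pairs(
    binned: BinnedSpikes,
    units: pd.DataFrame,
    jitter: JitterConfig | None = None,
    max_lag_ms: int = DEFAULT_MAX_LAG_MS,
    threshold_sd: float = SIGNIFICANCE_SD,
    peak_window_ms: float = PEAK_LAG_WINDOW_MS,
    double_count_flags: pd.DataFrame | None = None,
    exclude_flagged: bool = True,
    keep_all_curves: bool = False,
) -> CcgSet:
    """Correlograms, peak features and metadata for all unordered unit pairs.

    Uses one batched FFT pass over trials per unit, so the all-pairs sweep is
    O(U² · M · N log N) with small constants.  Flagged double-count pairs are
    excluded from the significant subset (configurable) but retained with
    their flag in the output table.
    """
    jitter = jitter or JitterConfig()
    n_units = binned.n_units
    m, n = binned.n_trials, binned.n_bins
    max_lag = _bins_for_ms(max_lag_ms, binned.bin_width_s)
    lags = _lag_axis(max_lag) * binned.bin_width_s * 1e3
    theta = (n - np.abs(_lag_axis(max_lag))).astype(float)

    wbins = jitter.window_bins(binned.bin_width_s)
    nfft = sp_fft.next_fast_len(n + max_lag + 1)
    fx = sp_fft.rfft(binned.x.astype(float), n=nfft, axis=2)
    rates = np.stack([expected_jitter_rates(binned.x[u], wbins) for u in range(n_units)])
    fr = sp_fft.rfft(rates, n=nfft, axis=2)
    lam = binned.lambda_per_bin

    depths = units.set_index("unit_id")["depth_um"]
    layers = units.set_index("unit_id")["layer"]
    flagged_set: set[frozenset] = set()
    if double_count_flags is not None and len(double_count_flags):
        for _, r in double_count_flags[double_count_flags["flagged"]].iterrows():
            flagged_set.add(frozenset((int(r["unit_a"]), int(r["unit_b"]))))

    def _corr_pair(fa_row, fb_row, integral=False):
        spec = np.einsum("mf,mf->f", np.conj(fa_row), fb_row)
        cc = sp_fft.irfft(spec, n=nfft)
        out = np.empty(2 * max_lag + 1)
        out[max_lag:] = cc[: max_lag + 1]
        out[:max_lag] = cc[nfft - max_lag :]
        return np.rint(out) if integral else out

    rows = []
    curves: dict[tuple[int, int], np.ndarray] = {}
    for a in range(n_units):
        for b in range(a + 1, n_units):
            ja, jb = int(binned.unit_ids[a]), int(binned.unit_ids[b])
            norm = m * theta * np.sqrt(lam[a] * lam[b])
            raw = _corr_pair(fx[a], fx[b], integral=True) / norm
            jit = _corr_pair(fr[a], fr[b]) / norm
            corr = raw - jit
            curve = CcgCurve(ja, jb, lags_ms=lags, raw=raw, jittered=jit,
                             corrected=corr, theta=theta)
            pf = detect_peak(curve, peak_window_ms=peak_window_ms,
                             threshold_sd=threshold_sd)
            dc_flag = frozenset((ja, jb)) in flagged_set
            excluded = dc_flag and exclude_flagged
            if keep_all_curves or (pf.significant and not excluded):
                curves[(ja, jb)] = corr
            rows.append(
                dict(
                    ref_unit=ja,
                    target_unit=jb,
                    peak_lag_ms=pf.peak_lag_ms,
                    peak_efficacy=pf.peak_efficacy,
                    z_peak=pf.z_peak,
                    significant=pf.significant,
                    trough_lag_ms=pf.trough_lag_ms,
                    z_trough=pf.z_trough,
                    significant_trough=pf.significant_trough,
                    noise_mean=pf.noise_mean,
                    noise_sd=pf.noise_sd,
                    distance_um=float(abs(depths[ja] - depths[jb])),
                    layer_ref=layers[ja],
                    layer_target=layers[jb],
                    double_count_flag=dc_flag,
                    excluded=excluded,
                )
            )
    pairs = pd.DataFrame(rows)
    logger.info(
        "compute_all_pairs: %d pairs, %d significant",
        len(pairs),
        int(pairs["significant"].sum()) if len(pairs) else 0,
    )
    return CcgSet(pairs=pairs, lags_ms=lags, curves=curves)


def significance_table(ccg_set: CcgSet, thresholds=range(1, 8)) -> pd.DataFrame:
    """Counts of pairs with peaks above / troughs below n SDs of the noise."""
    rows = []
    p = ccg_set.pairs
    for sd in thresholds:
        rows.append(
            dict(
                threshold_sd=sd,
                peaks_above=int((p["z_peak"] > sd).sum()),
                troughs_below=int((p["z_trough"] < -sd).sum()),
            )
        )
    return pd.DataFrame(rows)
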