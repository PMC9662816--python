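"""Tabular domain types, file I/O, spike binning and inclusion filters.

Spike data live in three cross-referential tables:

- spikes: one row per spike (``unit_id``, ``trial_id``, ``time_s``), times in
  seconds relative to trial onset;
- trials: one row per stimulus presentation (``trial_id``, ``direction_deg``,
  ``spatial_freq_cpd``, ``onset_s``, ``duration_s``);
- units: one row per unit (``unit_id``, ``depth_um``, ``layer``,
  ``mean_rate_hz``).  Depth is signed, 0 at the layer-4c/5 border, negative
  values are deeper.

All downstream correlogram math runs on :class:`BinnedSpikes`, a per-unit
trial-by-bin binary array with half-open 1-ms bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: layer labels accepted in the units table
ALLOWED_LAYERS = ("2/3", "4A/B", "4cα", "4cβ", "5", "6", "unknown")

SPIKE_COLUMNS = ("unit_id", "trial_id", "time_s")
TRIAL_COLUMNS = ("trial_id", "direction_deg", "spatial_freq_cpd", "onset_s", "duration_s")
UNIT_COLUMNS = ("unit_id", "depth_um", "layer")  # mean_rate_hz optional on input


class SchemaError(ValueError):
    """Raised when an input table violates the column schema or referential integrity."""


@dataclass
class BinnedSpikes:
    """Per-unit binary spike arrays on a common trial-by-bin grid.

    Attributes
    ----------
    window : tuple of float
        Analysis window ``(t0_s, t1_s)`` within the trial.
    bin_width_s : float
        Bin width in seconds (default 1 ms).
    unit_ids : ndarray of int
        Unit ids, aligned with the first axis of ``x``.
    x : ndarray, shape (n_units, M, N)
        Binary spike indicators; ``x[u, i, t]`` is 1 if unit ``u`` fired in
        bin ``t`` of trial ``i``.
    trial_ids : ndarray of int
        Trial ids, aligned with the second axis of ``x``.
    n_clipped : int
        Number of spikes discarded because more than one fell in a single bin.
    """

    window: tuple[float, float]
    bin_width_s: float
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    x: np.ndarray
    n_clipped: int = 0
    lambda_per_bin: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.x.ndim != 3:
            raise ValueError("x must have shape (n_units, M, N)")
        self.lambda_per_bin = self.x.mean(axis=(1, 2))

    @property
    def n_units(self) -> int:
        return self.x.shape[0]

    @property
    def n_trials(self) -> int:
        return self.x.shape[1]

    @property
    def n_bins(self) -> int:
        return self.x.shape[2]

    def index_of(self, unit_id: int) -> int:
        idx = np.flatnonzero(self.unit_ids == unit_id)
        if idx.size == 0:
            raise KeyError(f"unit {unit_id} not in BinnedSpikes")
        return int(idx[0])

    def rates_hz(self) -> np.ndarray:
        """Mean firing rate per unit in spikes/s over the analysis window."""
        return self.lambda_per_bin / self.bin_width_s

    def subset(self, keep: np.ndarray) -> "BinnedSpikes":
        """Return a new BinnedSpikes restricted to a boolean/index unit mask."""
        return BinnedSpikes(
            window=self.window,
            bin_width_s=self.bin_width_s,
            unit_ids=self.unit_ids[keep],
            trial_ids=self.trial_ids,
            x=self.x[keep],
            n_clipped=self.n_clipped,
        )


def _require_columns(df: pd.DataFrame, columns, path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _require_numeric(df: pd.DataFrame, columns, path: str) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {row}")
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SchemaError(f"{path}: missing value in column {col!r} at row {row}")
        df[col] = coerced
    return df


def validate_trials(trials: pd.DataFrame, path: str = "trials") -> pd.DataFrame:
    _require_columns(trials, TRIAL_COLUMNS, path)
    trials = trials.copy()
    _require_numeric(trials, TRIAL_COLUMNS, path)
    if trials["trial_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate trial_id")
    if ((trials["direction_deg"] < 0) | (trials["direction_deg"] >= 360)).any():
        raise SchemaError(f"{path}: direction_deg outside [0, 360)")
    if (trials["duration_s"] <= 0).any():
        raise SchemaError(f"{path}: non-positive duration_s")
    trials["trial_id"] = trials["trial_id"].astype(int)
    return trials


def validate_units(units: pd.DataFrame, path: str = "units") -> pd.DataFrame:
    _require_columns(units, UNIT_COLUMNS, path)
    units = units.copy()
    _require_numeric(units, ["unit_id", "depth_um"], path)
    if units["unit_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate unit_id")
    bad_layer = ~units["layer"].isin(ALLOWED_LAYERS)
    if bad_layer.any():
        row = int(np.flatnonzero(bad_layer.to_numpy())[0])
        raise SchemaError(
            f"{path}: unknown layer {units['layer'].iloc[row]!r} at row {row}; "
            f"allowed: {ALLOWED_LAYERS}"
        )
    units["unit_id"] = units["unit_id"].astype(int)
    if "mean_rate_hz" not in units.columns:
        units["mean_rate_hz"] = np.nan
    return units


def validate_spikes(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    units: pd.DataFrame,
    path: str = "spikes",
) -> pd.DataFrame:
    _require_columns(spikes, SPIKE_COLUMNS, path)
    spikes = spikes.copy()
    if len(spikes):
        _require_numeric(spikes, SPIKE_COLUMNS, path)
        spikes["unit_id"] = spikes["unit_id"].astype(int)
        spikes["trial_id"] = spikes["trial_id"].astype(int)
        unknown_unit = ~spikes["unit_id"].isin(units["unit_id"])
        if unknown_unit.any():
            row = int(np.flatnonzero(unknown_unit.to_numpy())[0])
            raise SchemaError(
                f"{path}: unit_id {spikes['unit_id'].iloc[row]} at row {row} "
                "absent from units table"
            )
        unknown_trial = ~spikes["trial_id"].isin(trials["trial_id"])
        if unknown_trial.any():
            row = int(np.flatnonzero(unknown_trial.to_numpy())[0])
            raise SchemaError(
                f"{path}: trial_id {spikes['trial_id'].iloc[row]} at row {row} "
                "absent from trials table"
            )
        durations = trials.set_index("trial_id")["duration_s"]
        dur = spikes["trial_id"].map(durations).to_numpy()
        t = spikes["time_s"].to_numpy()
        if ((t < 0) | (t > dur)).any():
            row = int(np.flatnonzero((t < 0) | (t > dur))[0])
            raise SchemaError(f"{path}: time_s outside [0, duration] at row {row}")
    else:
        spikes = spikes.astype({"unit_id": int, "trial_id": int, "time_s": float})
    return spikes


def load_dataset(spike_path, trial_path, unit_path):
    """Load and cross-validate the three CSV tables.

    Returns ``(spikes, trials, units)`` as pandas DataFrames.  Raises
    :class:`SchemaError` naming the offending file and row on any violation.
    """
    trials = validate_trials(pd.read_csv(trial_path), str(trial_path))
    units = validate_units(pd.read_csv(unit_path), str(unit_path))
    spikes = validate_spikes(pd.read_csv(spike_path), trials, units, str(spike_path))
    logger.info(
        "loaded %d spikes, %d trials, %d units", len(spikes), len(trials), len(units)
    )
    return spikes, trials, units


def save_dataset(spikes, trials, units, out_dir) -> None:
    """Write the three tables as CSV files into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes.to_csv(out / "spikes.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    units.to_csv(out / "units.csv", index=False)


def bin_spikes(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    units: pd.DataFrame,
    window: tuple[float, float] = (0.4, 1.0),
    bin_width_s: float = 0.001,
) -> BinnedSpikes:
    """Bin spike times into per-unit trial-by-bin binary arrays.

    Bins are half-open ``[t, t + bin_width)``.  Spikes outside the window are
    dropped; a bin receiving more than one spike is clipped to 1 and the clip
    count recorded.
    """
    t0, t1 = window
    if bin_width_s <= 0:
        raise ValueError("bin_width must be positive")
    if t0 < 0 or (len(trials) and t1 > trials["duration_s"].max() + 1e-12):
        raise ValueError(f"window {window} outside trial duration")
    n_bins = int(round((t1 - t0) / bin_width_s))
    if abs(n_bins * bin_width_s - (t1 - t0)) > bin_width_s:
        raise ValueError("bin_width does not divide the analysis window")

    unit_ids = units["unit_id"].to_numpy()
    trial_ids = np.sort(trials["trial_id"].to_numpy())
    unit_pos = {u: i for i, u in enumerate(unit_ids)}
    trial_pos = {t: i for i, t in enumerate(trial_ids)}

    x = np.zeros((len(unit_ids), len(trial_ids), n_bins), dtype=np.uint8)
    n_clipped = 0
    if len(spikes):
        t = spikes["time_s"].to_numpy()
        in_win = (t >= t0) & (t < t1)
        sel = spikes.loc[in_win]
        # small epsilon keeps boundary times (e.g. 0.5 - 0.4 in floats) in the
        # half-open bin they belong to
        bins = np.floor((sel["time_s"].to_numpy() - t0) / bin_width_s + 1e-9).astype(np.int64)
        bins = np.clip(bins, 0, n_bins - 1)
        ui = np.fromiter((unit_pos[u] for u in sel["unit_id"]), dtype=np.int64, count=len(sel))
        ti = np.fromiter((trial_pos[t] for t in sel["trial_id"]), dtype=np.int64, count=len(sel))
        counts = np.zeros(x.shape, dtype=np.int32)
        np.add.at(counts, (ui, ti, bins), 1)
        n_clipped = int((counts[counts > 1] - 1).sum())
        if n_clipped:
            logger.info("bin_spikes: clipped %d coincident spike(s) to binary bins", n_clipped)
        x = (counts > 0).astype(np.uint8)

    return BinnedSpikes(
        window=(t0, t1),
        bin_width_s=bin_width_s,
        unit_ids=unit_ids,
        trial_ids=trial_ids,
        x=x,
        n_clipped=n_clipped,
    )


def filter_units_by_rate(binned: BinnedSpikes, min_rate_hz: float = 3.0) -> BinnedSpikes:
    """Drop units firing below ``min_rate_hz`` in the analysis window (inclusive bound)."""
    rates = binned.rates_hz()
    keep = rates >= min_rate_hz - 1e-9  # inclusive bound, robust to FP rounding
    dropped = binned.unit_ids[~keep]
    if dropped.size:
        logger.info("filter_units_by_rate: removed units %s", dropped.tolist())
    if not keep.any():
        logger.warning("filter_units_by_rate: all units removed")
    return binned.subset(keep)
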