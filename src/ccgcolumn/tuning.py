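"""Per-unit visual response statistics and pairwise signal correlations.

Covers trial-wise evoked rates (30-ms latency offset), direction tuning
curves, the F1/F0 modulation ratio with the simple/complex split, and the
orientation signal correlation r_ori (Pearson correlation of two units'
36-direction mean-response vectors over the full 1-s stimulus window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_LATENCY_S = 0.030


@dataclass
class TuningProfile:
    unit_id: int
    directions_deg: np.ndarray
    mean_response: np.ndarray  # spikes/s per direction
    preferred_direction_deg: float
    f0: float = np.nan
    f1: float = np.nan
    modulation_ratio: float = np.nan
    cell_class: str = "unclassified"  # "simple" | "complex" | "unclassified"


@dataclass
class PairTuning:
    unit_a: int
    unit_b: int
    r_ori: float
    flagged: bool = False


def cell_class_from_ratio(modulation_ratio: float) -> str:
    """Simple iff F1/F0 strictly exceeds 1; a ratio of exactly 1 is complex."""
    if not np.isfinite(modulation_ratio):
        return "unclassified"
    return "simple" if modulation_ratio > 1 else "complex"


def trial_responses(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    latency_offset_s: float = DEFAULT_LATENCY_S,
) -> pd.DataFrame:
    """Mean evoked rate (spikes/s) per unit and trial.

    The response window is ``[latency, duration]`` within each trial — spikes
    are counted from the latency offset to stimulus offset and divided by the
    window length.
    """
    durations = trials.set_index("trial_id")["duration_s"]
    if (latency_offset_s >= durations).any():
        raise ValueError("latency offset exceeds a trial duration")
    rows = []
    trial_ids = trials["trial_id"].to_numpy()
    unit_ids = spikes["unit_id"].unique() if len(spikes) else np.array([], dtype=int)
    counts = pd.DataFrame(0.0, index=unit_ids, columns=trial_ids)
    if len(spikes):
        sel = spikes[spikes["time_s"] >= latency_offset_s]
        grouped = sel.groupby(["unit_id", "trial_id"]).size()
        for (u, t), c in grouped.items():
            counts.loc[u, t] = c
    for u in unit_ids:
        for t in trial_ids:
            window = durations[t] - latency_offset_s
            rows.append(dict(unit_id=int(u), trial_id=int(t), rate_hz=counts.loc[u, t] / window))
    return pd.DataFrame(rows, columns=["unit_id", "trial_id", "rate_hz"])


def tuning_curve(responses: pd.DataFrame, trials: pd.DataFrame, unit_id: int) -> TuningProfile:
    """Direction tuning curve of one unit: per-direction mean over repeats.

    Preferred direction is the argmax; exact ties break toward the smallest
    angle.  Raises if any direction has no trials.
    """
    merged = responses[responses["unit_id"] == unit_id].merge(
        trials[["trial_id", "direction_deg"]], on="trial_id"
    )
    directions = np.sort(trials["direction_deg"].unique())
    by_dir = merged.groupby("direction_deg")["rate_hz"].mean()
    missing = [d for d in directions if d not in by_dir.index]
    if missing:
        raise ValueError(f"unit {unit_id}: no trials for direction(s) {missing}")
    curve = by_dir.reindex(directions).to_numpy()
    best = directions[np.flatnonzero(curve == curve.max())[0]]
    if (curve == curve.max()).sum() > 1:
        logger.info("unit %d: tied preferred direction, taking smallest angle", unit_id)
    return TuningProfile(
        unit_id=int(unit_id),
        directions_deg=directions,
        mean_response=curve,
        preferred_direction_deg=float(best),
    )


def psth(
    spikes: pd.DataFrame,
    trial_ids,
    duration_s: float,
    bin_width_s: float = 0.001,
) -> np.ndarray:
    """Pooled-repeat PSTH (spikes/s) over ``trial_ids`` at 1-ms resolution."""
    n_bins = int(round(duration_s / bin_width_s))
    sel = spikes[spikes["trial_id"].isin(trial_ids)]
    bins = np.floor(sel["time_s"].to_numpy() / bin_width_s).astype(int)
    bins = np.clip(bins, 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    return counts / (len(trial_ids) * bin_width_s)


def modulation_ratio(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    profile: TuningProfile,
    stimulus_tf_hz: float,
    bin_width_s: float = 0.001,
) -> TuningProfile:
    """Complete a profile with F0, F1 and the simple/complex label.

    F0 is the mean of the pooled-repeat PSTH at the preferred direction, F1
    the magnitude of its Fourier component at the stimulus temporal frequency
    (single-sided amplitude).  Simple iff F1/F0 > 1 (strict); zero F0 leaves
    the unit unclassified.
    """
    pref_trials = trials.loc[
        trials["direction_deg"] == profile.preferred_direction_deg, "trial_id"
    ]
    duration = float(trials["duration_s"].iloc[0])
    unit_spikes = spikes[spikes["unit_id"] == profile.unit_id]
    rate = psth(unit_spikes, pref_trials, duration, bin_width_s)
    n = rate.size
    f0 = float(rate.mean())
    freqs = np.fft.rfftfreq(n, d=bin_width_s)
    k = int(np.argmin(np.abs(freqs - stimulus_tf_hz)))
    f1 = float(2.0 * np.abs(np.fft.rfft(rate)[k]) / n)
    profile.f0 = f0
    profile.f1 = f1
    if f0 <= 0:
        profile.modulation_ratio = np.nan
        profile.cell_class = "unclassified"
        logger.warning("unit %d: zero F0, modulation ratio undefined", profile.unit_id)
    else:
        profile.modulation_ratio = f1 / f0
        profile.cell_class = cell_class_from_ratio(profile.modulation_ratio)
    return profile


def signal_correlation(profile_a: TuningProfile, profile_b: TuningProfile) -> PairTuning:
    """Pearson correlation of two units' per-direction mean responses."""
    a, b = profile_a.mean_response, profile_b.mean_response
    flagged = bool(np.std(a) == 0 or np.std(b) == 0)
    if flagged:
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return PairTuning(profile_a.unit_id, profile_b.unit_id, r_ori=r, flagged=flagged)


def tuning_table(profiles) -> pd.DataFrame:
    """Flatten profiles into the tuning.csv schema."""
    return pd.DataFrame(
        [
            dict(
                unit_id=p.unit_id,
                preferred_direction_deg=p.preferred_direction_deg,
                f0=p.f0,
                f1=p.f1,
                modulation_ratio=p.modulation_ratio,
                cell_class=p.cell_class,
            )
            for p in profiles
        ]
    )


def compute_tuning(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    units: pd.DataFrame,
    stimulus_tf_hz: float,
    latency_offset_s: float = DEFAULT_LATENCY_S,
    response_window: str = "full",
) -> dict[int, TuningProfile]:
    """Tuning profiles for every unit.

    ``response_window='full'`` uses the whole stimulus (latency 0) for the
    per-direction means entering r_ori; ``'evoked'`` applies the latency
    offset.
    """
    offset = 0.0 if response_window == "full" else latency_offset_s
    responses = trial_responses(spikes, trials, latency_offset_s=offset)
    profiles = {}
    for u in units["unit_id"]:
        if int(u) not in set(responses["unit_id"]):
            # silent unit: flat zero curve
            directions = np.sort(trials["direction_deg"].unique())
            profiles[int(u)] = TuningProfile(
                unit_id=int(u),
                directions_deg=directions,
                mean_response=np.zeros(len(directions)),
                preferred_direction_deg=float(directions[0]),
            )
            continue
        prof = tuning_curve(responses, trials, int(u))
        profiles[int(u)] = modulation_ratio(spikes, trials, prof, stimulus_tf_hz)
    return profiles
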