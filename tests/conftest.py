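"""Shared fixtures: tiny hand-checkable datasets and synthetic CCG sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ccgcolumn.correlogram import CcgSet
from ccgcolumn.data_model import BinnedSpikes


@pytest.fixture
def hand_binned() -> BinnedSpikes:
    """M=1, N=6; unit 0 spikes at bins {1,3}, unit 1 at bins {2,4}."""
    x = np.zeros((2, 1, 6), dtype=np.uint8)
    x[0, 0, [1, 3]] = 1
    x[1, 0, [2, 4]] = 1
    return BinnedSpikes(
        window=(0.0, 0.006),
        bin_width_s=0.001,
        unit_ids=np.array([0, 1]),
        trial_ids=np.array([0]),
        x=x,
    )


@pytest.fixture
def tiny_tables():
    """A 2-unit, 2-trial dataset with a handful of spikes."""
    trials = pd.DataFrame(
        dict(
            trial_id=[0, 1],
            direction_deg=[0.0, 90.0],
            spatial_freq_cpd=[2.0, 2.0],
            onset_s=[0.0, 1.25],
            duration_s=[1.0, 1.0],
        )
    )
    units = pd.DataFrame(
        dict(
            unit_id=[0, 1],
            depth_um=[100.0, -50.0],
            layer=["4cβ", "5"],
            mean_rate_hz=[np.nan, np.nan],
        )
    )
    spikes = pd.DataFrame(
        dict(
            unit_id=[0, 0, 1, 1, 1],
            trial_id=[0, 1, 0, 0, 1],
            time_s=[0.5, 0.25, 0.1, 0.9, 0.45],
        )
    )
    return spikes, trials, units


def bump(lags: np.ndarray, center: float, sd: float, amplitude: float = 1.0) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((lags - center) / sd) ** 2)


def make_ccg_set(curves_by_pair: dict, meta: pd.DataFrame | None = None) -> CcgSet:
    """Assemble a CcgSet from {(ref, target): corrected_curve} over ±100 ms.

    ``meta`` may supply distance_um / layer / r_ori columns indexed like the
    pair list; everything else is filled with analysis of the given curves.
    """
    from ccgcolumn.correlogram import CcgCurve, detect_peak

    lags = np.arange(-100, 101, dtype=float)
    rows, stored = [], {}
    for i, ((ref, tgt), curve) in enumerate(curves_by_pair.items()):
        curve = np.asarray(curve, float)
        pf = detect_peak(CcgCurve(ref, tgt, lags_ms=lags, corrected=curve))
        row = dict(
            ref_unit=ref,
            target_unit=tgt,
            peak_lag_ms=pf.peak_lag_ms,
            peak_efficacy=pf.peak_efficacy,
            z_peak=pf.z_peak,
            significant=True,
            excluded=False,
            distance_um=0.0,
            layer_ref="unknown",
            layer_target="unknown",
        )
        if meta is not None:
            row.update(meta.iloc[i].to_dict())
        rows.append(row)
        stored[(ref, tgt)] = curve
    return CcgSet(pairs=pd.DataFrame(rows), lags_ms=lags, curves=stored)
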