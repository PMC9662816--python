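"""Current-source-density profiles from laminar LFP and layer assignment.

CSD is the second spatial derivative of the trial-averaged LFP along the
probe, taken with the five-point stencil over ±2 depth samples, smoothed
across depth with a Gaussian kernel.  Sinks are negative.  The lower boundary
of the major sink (its sink→source reversal) anchors the layer-4c/5 border,
and a thickness table stacks the remaining laminar boundaries from there.

Depth follows the unit-table convention: 0 at the anchor, negative is deeper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: illustrative laminar thicknesses (µm), superficial → deep; replace with
#: histological estimates for real data
DEFAULT_THICKNESS_UM = {
    "2/3": 440.0,
    "4A/B": 200.0,
    "4cα": 180.0,
    "4cβ": 180.0,
    "5": 250.0,
    "6": 450.0,
}


@dataclass
class LfpProfile:
    """Trial-averaged LFP: depth (µm, ascending, uniform) × time (s)."""

    depth_um: np.ndarray
    time_s: np.ndarray
    potential: np.ndarray  # (n_depths, n_times)

    @property
    def spacing_um(self) -> float:
        dz = np.diff(self.depth_um)
        if dz.size and not np.allclose(dz, dz[0]):
            raise ValueError("non-uniform depth spacing")
        return float(dz[0]) if dz.size else np.nan


@dataclass
class CsdProfile:
    depth_um: np.ndarray  # interior grid where the stencil fits
    time_s: np.ndarray
    csd: np.ndarray  # (n_interior_depths, n_times); sinks negative
    anchor_depth_um: float | None = None


def compute_csd(lfp: LfpProfile) -> CsdProfile:
    """Five-point second spatial derivative; two-sample margins trimmed.

    CSD(z_i) ∝ −(φ_{i−2} − 2·φ_i + φ_{i+2}) / (2h)² with conductivity 1, so
    only sink/source geometry is meaningful.
    """
    phi = np.asarray(lfp.potential, float)
    if phi.shape[0] < 5:
        raise ValueError("need at least 5 depth samples")
    h = lfp.spacing_um  # validates uniform spacing
    csd = -(phi[:-4] - 2 * phi[2:-2] + phi[4:]) / (2 * h) ** 2
    return CsdProfile(depth_um=lfp.depth_um[2:-2], time_s=lfp.time_s, csd=csd)


def smooth_csd(csd: CsdProfile, sigma_um: float = 120.0) -> CsdProfile:
    """Gaussian smoothing along depth with reflected boundaries; σ=0 is identity."""
    if sigma_um < 0:
        raise ValueError("sigma must be non-negative")
    if sigma_um == 0:
        return CsdProfile(csd.depth_um, csd.time_s, csd.csd.copy(), csd.anchor_depth_um)
    h = float(np.diff(csd.depth_um)[0])
    smoothed = ndimage.gaussian_filter1d(csd.csd, sigma=sigma_um / abs(h), axis=0, mode="reflect")
    return CsdProfile(csd.depth_um, csd.time_s, smoothed, csd.anchor_depth_um)


def locate_anchor(csd: CsdProfile, response_window: tuple[float, float]) -> float:
    """Depth of the sink→source reversal just below the major sink.

    The time-averaged CSD over ``response_window`` is scanned for its most
    negative sample (major sink); the anchor is the linearly interpolated
    zero crossing on the deeper side.  Raises if no reversal exists.
    """
    t0, t1 = response_window
    sel = (csd.time_s >= t0) & (csd.time_s <= t1)
    if not sel.any():
        raise ValueError("response window outside the time grid")
    profile = csd.csd[:, sel].mean(axis=1)
    if (profile >= 0).all():
        raise ValueError("no sink in the time-averaged CSD")
    i_sink = int(np.argmin(profile))
    # walk deeper (toward smaller depth values) until the sign flips
    for i in range(i_sink, 0, -1):
        if profile[i - 1] >= 0 > profile[i]:
            frac = profile[i] / (profile[i] - profile[i - 1])
            anchor = csd.depth_um[i] + frac * (csd.depth_um[i - 1] - csd.depth_um[i])
            csd.anchor_depth_um = float(anchor)
            return float(anchor)
    raise ValueError("no sink/source reversal below the major sink")


def boundaries_from_thickness(
    thickness_um: dict | None = None, anchor_depth_um: float = 0.0
) -> dict:
    """Stack laminar (top, bottom) intervals around the 4c/5 border anchor.

    The table lists layers superficial → deep; the boundary between the last
    '4…' layer and the first deeper layer is pinned at the anchor.
    """
    thickness = dict(thickness_um or DEFAULT_THICKNESS_UM)
    if any(t <= 0 for t in thickness.values()):
        raise ValueError("thickness table entries must be positive (overlap otherwise)")
    layers = list(thickness.keys())
    deep_start = next(i for i, name in enumerate(layers) if name in ("5", "6"))
    bounds = {}
    top = anchor_depth_um
    for name in reversed(layers[:deep_start]):
        bounds[name] = (top + thickness[name], top)
        top += thickness[name]
    bottom = anchor_depth_um
    for name in layers[deep_start:]:
        bounds[name] = (bottom, bottom - thickness[name])
        bottom -= thickness[name]
    # re-order superficial → deep
    return {name: bounds[name] for name in layers}


def assign_layers(
    depths_um: np.ndarray,
    anchor_depth_um: float = 0.0,
    thickness_um: dict | None = None,
) -> list:
    """Map unit depths to layer labels using half-open (bottom, top] intervals.

    A unit exactly at a boundary goes to the deeper layer (so the anchor depth
    itself is layer 5); depths outside the stacked table are 'unknown'.
    """
    bounds = boundaries_from_thickness(thickness_um, anchor_depth_um)
    tops = [b[0] for b in bounds.values()]
    bots = [b[1] for b in bounds.values()]
    for (t1, b1), (t2, b2) in zip(zip(tops, bots), zip(tops[1:], bots[1:])):
        if not np.isclose(b1, t2):
            raise ValueError("overlapping or gapped thickness table entries")
    labels = []
    for d in np.asarray(depths_um, float):
        label = "unknown"
        for name, (top, bottom) in bounds.items():
            if bottom < d <= top:
                label = name
                break
        labels.append(label)
    return labels
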