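"""Synthetic cortical column: trial-structured spike trains with ground truth.

The generator is test scaffolding, deliberately segregated from the analysis
code: it produces depth-annotated, direction-tuned spike tables with planted
monosynaptic connections, common-input groups, stimulus locking and slow
shared rate modulation, together with a :class:`GroundTruth` record against
which the analysis stages are scored.

Background spikes are drawn by Bernoulli thinning of per-bin rates on the
1-ms grid of the data model; injection operators only ever add spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import validate_spikes, validate_trials, validate_units

DEFAULT_LAYER_BOUNDARIES = {
    # layer -> (top, bottom) depth in µm; 0 = 4c/5 border, negative deeper
    "2/3": (1000.0, 560.0),
    "4A/B": (560.0, 360.0),
    "4cα": (360.0, 180.0),
    "4cβ": (180.0, 0.0),
    "5": (0.0, -250.0),
    "6": (-250.0, -700.0),
}


@dataclass
class ColumnConfig:
    """Parameters of a synthetic column; all planted structure lives here."""

    n_units: int = 120
    depth_range_um: tuple[float, float] = (-700.0, 1000.0)
    layer_boundaries_um: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_BOUNDARIES))
    n_directions: int = 36
    n_repeats: int = 5
    trial_duration_s: float = 1.0
    stimulus_tf_hz: float = 4.0
    spatial_freq_cpd: float = 2.0
    bin_width_s: float = 0.001
    base_rate_mean_hz: float = 20.0
    base_rate_sd_hz: float = 5.0
    tuned_rate_mean_hz: float = 20.0
    kappa: float = 2.0
    preferred_scatter_deg: float = 15.0
    column_preferred_deg: float = 90.0
    fraction_simple: float = 0.3
    onset_amplitude_hz: float = 0.0
    onset_decay_s: float = 0.05
    slow_mod_amplitude: float = 0.0
    slow_mod_timescale_s: float = 0.1
    slow_mod_groups: list = field(default_factory=list)  # lists of unit indices
    # planted-interaction kernels
    n_monosynaptic: int = 0
    mono_efficacy_p: float = 0.3
    mono_delay_range_ms: tuple[float, float] = (1.0, 4.0)
    mono_jitter_sd_ms: float = 0.3
    n_common_input_groups: int = 0
    common_group_size: int = 2
    common_source_rate_hz: float = 20.0
    common_copy_p: float = 0.4
    common_jitter_sd_ms: float = 1.0
    distance_scale_um: float = 200.0  # exponential-distance kernel for partner choice
    tuning_similarity_weight: float = 1.0  # monotone weight on cos(Δpref)
    seed: int = 0

    def __post_init__(self) -> None:
        # YAML/JSON round trips deliver lists; normalise to tuples
        self.depth_range_um = tuple(self.depth_range_um)
        self.mono_delay_range_ms = tuple(self.mono_delay_range_ms)
        self.layer_boundaries_um = {
            k: tuple(v) for k, v in self.layer_boundaries_um.items()
        }
        if self.base_rate_mean_hz < 0 or self.tuned_rate_mean_hz < 0:
            raise ValueError("rates must be non-negative")
        if self.onset_amplitude_hz < 0 or self.slow_mod_amplitude < 0:
            raise ValueError("negative amplitudes are invalid")
        bounds = sorted(self.layer_boundaries_um.values(), key=lambda tb: -tb[0])
        for (t1, b1), (t2, b2) in zip(bounds, bounds[1:]):
            if b1 < t2 or t1 <= b1:
                raise ValueError("layer boundaries must be ordered and non-overlapping")


@dataclass
class Connection:
    kind: str  # "monosynaptic" | "common_input"
    members: tuple
    delay_ms: float = 0.0
    efficacy_p: float = 0.0
    jitter_sd_ms: float = 0.0
    source_rate_hz: float = 0.0


@dataclass
class GroundTruth:
    connections: list
    preferred_direction_deg: dict
    cell_class: dict

    def to_json(self, path) -> None:
        payload = dict(
            connections=[asdict(c) for c in self.connections],
            preferred_direction_deg={str(k): v for k, v in self.preferred_direction_deg.items()},
            cell_class={str(k): v for k, v in self.cell_class.items()},
        )
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            connections=[
                Connection(**{**c, "members": tuple(c["members"])})
                for c in payload["connections"]
            ],
            preferred_direction_deg={int(k): v for k, v in payload["preferred_direction_deg"].items()},
            cell_class={int(k): v for k, v in payload["cell_class"].items()},
        )


def von_mises_drive(direction_deg: np.ndarray, preferred_deg: float, kappa: float) -> np.ndarray:
    """Direction drive normalized to peak 1 at the preferred direction."""
    delta = np.deg2rad(direction_deg - preferred_deg)
    if np.isinf(kappa):
        return (np.isclose(np.cos(delta), 1.0)).astype(float)
    return np.exp(kappa * (np.cos(delta) - 1.0))


def half_wave_profile(t: np.ndarray, tf_hz: float) -> np.ndarray:
    """Half-wave-rectified sinusoid scaled to unit mean (F1/F0 = π/2)."""
    return np.pi * np.maximum(0.0, np.sin(2 * np.pi * tf_hz * t))


def make_trials(config: ColumnConfig, rng: np.random.Generator) -> pd.DataFrame:
    directions = np.arange(config.n_directions) * (360.0 / config.n_directions)
    dirs = np.repeat(directions, config.n_repeats)
    order = rng.permutation(len(dirs))
    dirs = dirs[order]
    df = pd.DataFrame(
        dict(
            trial_id=np.arange(len(dirs)),
            direction_deg=dirs,
            spatial_freq_cpd=config.spatial_freq_cpd,
            onset_s=np.arange(len(dirs)) * (config.trial_duration_s + 0.25),
            duration_s=config.trial_duration_s,
        )
    )
    return validate_trials(df)


def make_units(config: ColumnConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.depth_range_um
    depths = rng.uniform(lo, hi, size=config.n_units)
    layers = [assign_layer_from_boundaries(d, config.layer_boundaries_um) for d in depths]
    return validate_units(
        pd.DataFrame(
            dict(
                unit_id=np.arange(config.n_units),
                depth_um=depths,
                layer=layers,
                mean_rate_hz=np.nan,
            )
        )
    )


def assign_layer_from_boundaries(depth_um: float, boundaries: dict) -> str:
    """Half-open (bottom, top] intervals; a unit exactly on a border goes to
    the deeper layer."""
    for layer, (top, bottom) in boundaries.items():
        if bottom < depth_um <= top:
            return layer
    return "unknown"


def make_rate_profiles(
    config: ColumnConfig,
    trials: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """Per-unit, per-trial rate functions on the 1-ms grid.

    Returns ``rates`` of shape (n_units, n_trials, n_bins) in spikes/s and
    the ground-truth preferred directions / cell classes.  Simple units get a
    half-wave temporal profile (analytic F1/F0 = π/2 for a pure drive);
    complex units a flat temporal drive.  Optional additive onset transient
    and shared multiplicative slow modulation; rates clipped at 0.
    """
    n_bins = int(round(config.trial_duration_s / config.bin_width_s))
    t = (np.arange(n_bins) + 0.5) * config.bin_width_s
    n_trials = len(trials)
    dirs = trials["direction_deg"].to_numpy()

    base = np.clip(
        rng.normal(config.base_rate_mean_hz, config.base_rate_sd_hz, config.n_units),
        0.5,
        None,
    )
    preferred = (
        config.column_preferred_deg
        + rng.normal(0.0, config.preferred_scatter_deg, config.n_units)
    ) % 360.0
    simple = rng.random(config.n_units) < config.fraction_simple

    slow_group = np.full(config.n_units, -1)
    for gi, members in enumerate(config.slow_mod_groups):
        for u in members:
            slow_group[u] = gi

    rates = np.empty((config.n_units, n_trials, n_bins))
    hw = half_wave_profile(t, config.stimulus_tf_hz)
    onset = config.onset_amplitude_hz * np.exp(-t / config.onset_decay_s)

    # per-trial shared slow modulation phase, one per group
    n_groups = len(config.slow_mod_groups)
    phases = rng.uniform(0, 2 * np.pi, size=(max(n_groups, 1), n_trials))

    for u in range(config.n_units):
        drive = von_mises_drive(dirs, preferred[u], config.kappa)  # (n_trials,)
        # simple cells: the whole response follows the half-wave temporal
        # profile (unit mean), so F1/F0 = pi/2 regardless of base rate
        temporal = hw if simple[u] else np.ones(n_bins)
        r = (base[u] + config.tuned_rate_mean_hz * drive[:, None]) * temporal[None, :]
        r = r + onset[None, :]
        if config.slow_mod_amplitude > 0 and slow_group[u] >= 0:
            phase = phases[slow_group[u]][:, None]
            factor = 1.0 + config.slow_mod_amplitude * np.sin(
                2 * np.pi * t[None, :] / config.slow_mod_timescale_s + phase
            )
            r = r * factor
        rates[u] = np.clip(r, 0.0, None)

    truth = GroundTruth(
        connections=[],
        preferred_direction_deg={u: float(preferred[u]) for u in range(config.n_units)},
        cell_class={u: ("simple" if simple[u] else "complex") for u in range(config.n_units)},
    )
    return rates, truth


def sample_background(
    rates: np.ndarray, bin_width_s: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Bernoulli thinning of per-bin rates into a spike table.

    Spike times get a uniform sub-bin offset so that sub-ms screens (double
    counting) remain meaningful.
    """
    n_units, n_trials, n_bins = rates.shape
    p = np.clip(rates * bin_width_s, 0.0, 1.0)
    hits = rng.random(p.shape) < p
    u, tr, b = np.nonzero(hits)
    offs = rng.random(u.size)
    return pd.DataFrame(
        dict(unit_id=u, trial_id=tr, time_s=(b + offs) * bin_width_s)
    ).sort_values(["unit_id", "trial_id", "time_s"], ignore_index=True)


def inject_monosynaptic(
    spikes: pd.DataFrame,
    pre_unit: int,
    post_unit: int,
    efficacy_p: float,
    delay_ms: float,
    jitter_sd_ms: float,
    duration_s: float,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Each presynaptic spike triggers a postsynaptic spike with probability
    ``efficacy_p`` at ``delay_ms`` plus zero-mean Gaussian jitter."""
    if pre_unit == post_unit:
        raise ValueError("pre and post unit must differ")
    if delay_ms <= 0:
        raise ValueError("monosynaptic delay must be positive")
    if jitter_sd_ms < 0:
        raise ValueError("jitter SD must be non-negative")
    pre = spikes[spikes["unit_id"] == pre_unit]
    if efficacy_p > 0 and len(pre):
        fire = rng.random(len(pre)) < efficacy_p
        src = pre[fire]
        lag = (delay_ms + rng.normal(0.0, jitter_sd_ms, size=len(src))) * 1e-3
        t_new = src["time_s"].to_numpy() + lag
        ok = (t_new >= 0) & (t_new <= duration_s)
        new = pd.DataFrame(
            dict(
                unit_id=post_unit,
                trial_id=src["trial_id"].to_numpy()[ok],
                time_s=t_new[ok],
            )
        )
        spikes = pd.concat([spikes, new], ignore_index=True)
    if truth is not None:
        truth.connections.append(
            Connection(
                kind="monosynaptic",
                members=(int(pre_unit), int(post_unit)),
                delay_ms=float(delay_ms),
                efficacy_p=float(efficacy_p),
                jitter_sd_ms=float(jitter_sd_ms),
            )
        )
    return spikes


def inject_common_input(
    spikes: pd.DataFrame,
    members,
    source_rate_hz: float,
    jitter_sd_ms: float,
    copy_p: float,
    trials: pd.DataFrame,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """A hidden Poisson source feeds every member with probability ``copy_p``
    per source spike, at zero-mean Gaussian lag with SD ``jitter_sd_ms``."""
    if len(members) < 2:
        raise ValueError("common input requires at least two members")
    if jitter_sd_ms < 0:
        raise ValueError("jitter SD must be non-negative")
    new_rows = []
    if copy_p > 0:
        for _, tr in trials.iterrows():
            dur = float(tr["duration_s"])
            n_src = rng.poisson(source_rate_hz * dur)
            src_times = np.sort(rng.uniform(0.0, dur, n_src))
            for m in members:
                take = rng.random(n_src) < copy_p
                t_new = src_times[take] + rng.normal(0.0, jitter_sd_ms * 1e-3, take.sum())
                ok = (t_new >= 0) & (t_new <= dur)
                for tt in t_new[ok]:
                    new_rows.append((int(m), int(tr["trial_id"]), float(tt)))
    if new_rows:
        spikes = pd.concat(
            [spikes, pd.DataFrame(new_rows, columns=["unit_id", "trial_id", "time_s"])],
            ignore_index=True,
        )
    if truth is not None:
        truth.connections.append(
            Connection(
                kind="common_input",
                members=tuple(int(m) for m in members),
                efficacy_p=float(copy_p),
                jitter_sd_ms=float(jitter_sd_ms),
                source_rate_hz=float(source_rate_hz),
            )
        )
    return spikes


def _pick_partner(
    u: int,
    depths: np.ndarray,
    preferred: np.ndarray,
    config: ColumnConfig,
    rng: np.random.Generator,
    exclude: set,
) -> int | None:
    """Partner choice: probability decays exponentially with depth distance and
    rises with tuning similarity."""
    n = len(depths)
    w = np.exp(-np.abs(depths - depths[u]) / config.distance_scale_um)
    sim = 0.5 * (1 + np.cos(np.deg2rad(preferred - preferred[u])))
    w = w * (1.0 + config.tuning_similarity_weight * sim)
    w[u] = 0.0
    for v in exclude:
        w[v] = 0.0
    if w.sum() <= 0:
        return None
    return int(rng.choice(n, p=w / w.sum()))


def generate_column(config: ColumnConfig, seed: int | None = None):
    """Full synthetic column: spikes, trials, units and ground truth.

    Deterministic for a fixed seed.  Interactions are planted after background
    sampling; partner choice follows an exponential-distance kernel weighted
    by tuning similarity.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trials = make_trials(config, rng)
    units = make_units(config, rng)
    rates, truth = make_rate_profiles(config, trials, rng)
    spikes = sample_background(rates, config.bin_width_s, rng)

    depths = units["depth_um"].to_numpy()
    preferred = np.array([truth.preferred_direction_deg[u] for u in range(config.n_units)])

    used: set = set()
    for _ in range(config.n_monosynaptic):
        candidates = [u for u in range(config.n_units) if u not in used]
        if len(candidates) < 2:
            break
        pre = int(rng.choice(candidates))
        post = _pick_partner(pre, depths, preferred, config, rng, used | {pre})
        if post is None:
            break
        delay = float(rng.uniform(*config.mono_delay_range_ms))
        spikes = inject_monosynaptic(
            spikes, pre, post, config.mono_efficacy_p, delay,
            config.mono_jitter_sd_ms, config.trial_duration_s, rng, truth,
        )
        used |= {pre, post}

    for _ in range(config.n_common_input_groups):
        candidates = [u for u in range(config.n_units) if u not in used]
        if len(candidates) < config.common_group_size:
            break
        anchor = int(rng.choice(candidates))
        members = [anchor]
        while len(members) < config.common_group_size:
            nxt = _pick_partner(anchor, depths, preferred, config, rng, used | set(members))
            if nxt is None:
                break
            members.append(nxt)
        if len(members) < 2:
            break
        spikes = inject_common_input(
            spikes, members, config.common_source_rate_hz,
            config.common_jitter_sd_ms, config.common_copy_p, trials, rng, truth,
        )
        used |= set(members)

    spikes = spikes.sort_values(["unit_id", "trial_id", "time_s"], ignore_index=True)
    spikes = validate_spikes(spikes, trials, units)
    rate = spikes.groupby("unit_id").size() / (len(trials) * config.trial_duration_s)
    units = units.copy()
    units["mean_rate_hz"] = units["unit_id"].map(rate).fillna(0.0)
    return spikes, trials, units, truth
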