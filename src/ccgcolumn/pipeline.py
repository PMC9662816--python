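"""End-to-end orchestration: simulate → tune → correlate → classify → summarize.

A single :class:`PipelineConfig` carries every threshold and seed; the run
writes module outputs plus a ``report.json`` aggregating counts, fits and
test results.  All stochastic stages draw from explicit seeds so reruns with
the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ccg_classes, column_stats, correlogram, data_model, synthetic, tuning

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults follow the analysis conventions."""

    # input / simulation
    simulate: bool = True
    data_dir: str | None = None
    column: synthetic.ColumnConfig = field(default_factory=synthetic.ColumnConfig)
    # binning
    window: tuple[float, float] = (0.4, 1.0)
    bin_width_s: float = 0.001
    min_rate_hz: float = 3.0
    # correlogram
    jitter_window_ms: float = 25.0
    max_lag_ms: int = 100
    threshold_sd: float = 7.0
    peak_window_ms: float = 10.0
    double_count_dist_um: float = 50.0
    double_count_coincidence_ms: float = 0.167
    double_count_frac: float = 0.20
    exclude_flagged: bool = True
    # classification
    cluster_seed: int = 0
    cluster_tol: float = 0.02
    perplexity: float = 30.0
    sharp_width_ms: float = 4.0
    force_k: int | None = None
    mono_max_width_ms: float = 5.0
    # statistics
    logistic_distance_range: tuple[float, float] = (86.0, 310.0)
    stats_seed: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        column_raw = raw.pop("column", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            column = synthetic.ColumnConfig(**column_raw)
        except TypeError as exc:
            raise ConfigError(f"bad column config: {exc}") from exc
        cfg = cls(column=column, **raw)
        if isinstance(cfg.window, list):
            cfg.window = tuple(cfg.window)
        if isinstance(cfg.logistic_distance_range, list):
            cfg.logistic_distance_range = tuple(cfg.logistic_distance_range)
        return cfg

    def to_dict(self) -> dict:
        def listify(v):
            if isinstance(v, tuple):
                return [listify(x) for x in v]
            if isinstance(v, dict):
                return {k: listify(x) for k, x in v.items()}
            if isinstance(v, list):
                return [listify(x) for x in v]
            return v

        return listify(dataclasses.asdict(self))


def _sanitize(obj):
    """Make a report JSON-safe: numpy → native types, non-finite → None."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return [_sanitize(r) for r in obj.to_dict(orient="records")]
    if isinstance(obj, pd.Series):
        return _sanitize(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _sanitize(dataclasses.asdict(obj))
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the report bundle into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data -----------------------------------------------------------
    if config.simulate:
        spikes, trials, units, truth = synthetic.generate_column(config.column, config.seed)
        data_model.save_dataset(spikes, trials, units, out / "data")
        truth.to_json(out / "data" / "ground_truth.json")
    else:
        if not config.data_dir:
            raise ConfigError("data_dir required when simulation is disabled")
        d = Path(config.data_dir)
        for name in ("spikes.csv", "trials.csv", "units.csv"):
            if not (d / name).exists():
                raise ConfigError(f"missing input file {d / name}")
        spikes, trials, units = data_model.load_dataset(
            d / "spikes.csv", d / "trials.csv", d / "units.csv"
        )
        truth = None

    # --- binning and filters -------------------------------------------
    binned = data_model.bin_spikes(spikes, trials, units, config.window, config.bin_width_s)
    binned = data_model.filter_units_by_rate(binned, config.min_rate_hz)
    if binned.n_units < 2:
        raise DataError("fewer than 2 units after rate filtering")
    units_kept = units[units["unit_id"].isin(binned.unit_ids)].reset_index(drop=True)

    # --- tuning ---------------------------------------------------------
    tf = config.column.stimulus_tf_hz
    profiles = tuning.compute_tuning(spikes, trials, units_kept, stimulus_tf_hz=tf)
    tuning_df = tuning.tuning_table(profiles.values())
    tuning_df.to_csv(out / "tuning.csv", index=False)

    # --- correlograms ---------------------------------------------------
    flags = correlogram.screen_double_counts(
        spikes[spikes["unit_id"].isin(binned.unit_ids)],
        units_kept,
        dist_um=config.double_count_dist_um,
        coincidence_ms=config.double_count_coincidence_ms,
        frac=config.double_count_frac,
    )
    jitter = correlogram.JitterConfig(window_ms=config.jitter_window_ms, mode="analytic")
    ccg_set = correlogram.compute_all_pairs(
        binned,
        units_kept,
        jitter=jitter,
        max_lag_ms=config.max_lag_ms,
        threshold_sd=config.threshold_sd,
        peak_window_ms=config.peak_window_ms,
        double_count_flags=flags,
        exclude_flagged=config.exclude_flagged,
    )
    # attach signal correlations
    r_ori = []
    for _, rec in ccg_set.pairs.iterrows():
        pt = tuning.signal_correlation(
            profiles[int(rec["ref_unit"])], profiles[int(rec["target_unit"])]
        )
        r_ori.append(pt.r_ori)
    ccg_set.pairs["r_ori"] = r_ori
    ccg_set.pairs.to_csv(out / "ccg_pairs.csv", index=False)
    sig_table = correlogram.significance_table(ccg_set)

    report: dict = dict(
        version=__version__,
        config=config.to_dict(),
        n_units=int(binned.n_units),
        n_trials=int(binned.n_trials),
        n_pairs=int(len(ccg_set.pairs)),
        n_significant=int(len(ccg_set.significant)),
        n_double_count_flagged=int(flags["flagged"].sum()) if len(flags) else 0,
        significance_table=sig_table,
    )

    # --- classification -------------------------------------------------
    sig = ccg_set.significant
    assignment = None
    if len(sig) >= 8:
        assignment = ccg_classes.assign_classes(
            ccg_set,
            seed=config.cluster_seed,
            tol=config.cluster_tol,
            perplexity=config.perplexity,
            force_k=config.force_k,
            sharp_width_ms=config.sharp_width_ms,
        )
        assignment.per_pair.to_csv(out / "classes.csv", index=False)
        assignment.evaluation.to_csv(out / "evaluation.csv", index=False)
        tmpl_rows = []
        for cid, curve in assignment.template_curves.items():
            cls = assignment.templates.set_index("cluster_id")["class_label"][cid]
            for lag, val in zip(np.arange(-10, 11), curve):
                tmpl_rows.append(dict(cluster_id=cid, class_label=cls, lag_ms=int(lag), value=val))
        pd.DataFrame(tmpl_rows).to_csv(out / "templates.csv", index=False)
        report["selected_k"] = int(assignment.k)
        report["class_counts"] = (
            assignment.per_pair["class_label"].value_counts().to_dict()
        )
        # merge class labels back onto the pair table (pair identity is unordered)
        key = lambda df: df.apply(  # noqa: E731
            lambda r: frozenset((int(r["ref_unit"]), int(r["target_unit"]))), axis=1
        )
        label_map = dict(zip(key(assignment.per_pair), assignment.per_pair["class_label"]))
        sig = sig.copy()
        sig["class_label"] = key(sig).map(label_map)
    else:
        logger.warning("too few significant pairs (%d) for clustering", len(sig))

    # --- statistics -----------------------------------------------------
    stats_report: dict = {}
    if len(sig) >= 10:
        abs_lag = sig["peak_lag_ms"].abs().to_numpy()
        dist = sig["distance_um"].to_numpy()
        slope, intercept, r = column_stats.fit_linear(dist, abs_lag, cost="MSE")
        stats_report["lag_vs_distance"] = dict(
            slope_ms_per_um=slope, intercept_ms=intercept, pearson_r=r,
            slope_ms_per_500um=slope * 500,
        )
        eff = sig["peak_efficacy"].to_numpy()
        keep = column_stats._iqr_mask(eff) & (eff > 0)
        if keep.sum() >= 10:
            med = column_stats.binned_relationship(
                dist[keep], eff[keep], stat="median", seed=config.stats_seed
            )
            try:
                a, lam, half, r_exp = column_stats.fit_exponential_decay(
                    med["bin_center"].to_numpy(), med["stat"].to_numpy(), cost="MAE"
                )
                stats_report["efficacy_vs_distance"] = dict(
                    amplitude=a, decay_constant_um=lam, half_distance_um=half, pearson_r=r_exp
                )
            except ValueError as exc:
                stats_report["efficacy_vs_distance"] = dict(error=str(exc))
        try:
            for target in ("peak_lag", "peak_efficacy"):
                res = column_stats.fit_standardized_regression(sig, target=target)
                stats_report[f"regression_{target}"] = dict(
                    intercept=res.intercept,
                    coefficients=dict(zip(res.predictor_names, res.coefficients)),
                    r_squared=res.r_squared,
                    n=res.n,
                )
        except ValueError as exc:
            stats_report["regression_error"] = str(exc)
        try:
            dm = column_stats.distance_match(sig)
            stats_report["distance_matching"] = {
                k: v for k, v in dm.items() if k != "matched"
            }
        except ValueError as exc:
            stats_report["distance_matching"] = dict(error=str(exc))
        # sharp-narrow, non-zero-lag screen for putative monosynapses
        n_cand = 0
        for _, rec in sig.iterrows():
            curve = ccg_set.curve(int(rec["ref_unit"]), int(rec["target_unit"]))
            n_cand += ccg_classes.monosynaptic_candidate(
                curve, ccg_set.lags_ms, rec["peak_lag_ms"],
                max_width_ms=config.mono_max_width_ms,
            )
        stats_report["monosynaptic_candidates"] = dict(
            n=int(n_cand), fraction_of_significant=n_cand / len(sig)
        )
        if "class_label" in sig and sig["class_label"].notna().sum() >= 10:
            comp = column_stats.class_composition_tests(sig)
            stats_report["composition"] = dict(
                within_between=comp["within_between"],
                chi_squared=comp["chi_squared"],
            )
            cell_class = tuning_df.set_index("unit_id")["cell_class"]
            stats_report["simple_complex"] = column_stats.simple_complex_direction_test(
                sig, cell_class
            )
    report["stats"] = stats_report

    if truth is not None:
        report["ground_truth"] = dict(
            n_connections=len(truth.connections),
            kinds=pd.Series([c.kind for c in truth.connections]).value_counts().to_dict()
            if truth.connections
            else {},
        )

    with open(out / "report.json", "w") as fh:
        json.dump(_sanitize(report), fh, indent=2, allow_nan=False)
    logger.info("pipeline complete: %s", out / "report.json")
    return report
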