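# ccgcolumn

Analysis pipeline for functional interactions among neurons recorded in a
single cortical column, built around jitter-corrected cross-correlograms
(CCGs) of trial-structured spike trains, plus a synthetic-column simulator
with planted ground-truth interactions for end-to-end validation.

## What it does

- **Data model** (`ccgcolumn.data_model`) — CSV spike/trial/unit tables,
  1-ms binary binning over a configurable analysis window (default
  0.4–1.0 s), minimum-rate inclusion filter (3 spikes/s).
- **Synthetic column** (`ccgcolumn.synthetic`) — direction-tuned,
  depth-annotated Poisson spike trains with planted monosynaptic
  connections, common-input groups, stimulus locking and slow shared rate
  modulation; ground truth saved alongside.
- **Tuning** (`ccgcolumn.tuning`) — direction tuning curves, F1/F0
  modulation ratio with the simple/complex split (simple iff F1/F0 > 1),
  and pairwise signal correlations (r_ori) over the 36 direction-wise mean
  responses.
- **Correlograms** (`ccgcolumn.correlogram`) — raw CCGs normalized by the
  triangular overlap factor θ(τ) = N − |τ| and the geometric mean rate;
  the 25-ms interval-jitter null in closed form (Monte-Carlo resampling
  kept as an oracle); corrected = raw − jittered; significance when the
  peak within ±10 ms exceeds 7 SDs of the 50–100 ms flank noise; trough
  counting; double-count screening (50 µm / 0.167 ms / 20 %).
- **CCG classes** (`ccgcolumn.ccg_classes`) — z-scored 21-lag shape
  features for both orderings of each significant pair, t-SNE to 3-D,
  k-means (k = 1…10, 50 replicates), elbow (η) + silhouette model
  selection, and semantic templates: `S_sync`, `B_sync`, `F_async`,
  `R_async`; sharp-narrow (<5 ms) monosynaptic-candidate screen.
- **Column statistics** (`ccgcolumn.column_stats`) — quantile-binned
  distance/tuning relationships, linear and exponential-decay fits
  (MSE/MAE), adjacent-sort distance matching, standardized OLS
  regressions with 1.5·IQR outlier trimming, composition chi-squared /
  z / rank-sum tests and layer logistic regressions.
- **CSD & layers** (`ccgcolumn.csd`) — five-point current-source-density
  from laminar LFP, 120-µm Gaussian smoothing, sink-reversal anchoring of
  the 4c/5 border, thickness-table layer assignment.

## CLI

```bash
# generate a synthetic column (spikes.csv, trials.csv, units.csv, ground_truth.json)
ccgcolumn simulate --out data/ --seed 1

# run the full pipeline on a simulated column
ccgcolumn all --config examples/column.yaml --out results/

# analyze an existing dataset directory
ccgcolumn analyze --data-dir data/ --out results/
```

All thresholds (7 SD, ±10 ms, 25 ms jitter window, 3 spikes/s, double-count
rule, clustering settings) are config keys; see
`ccgcolumn.pipeline.PipelineConfig` and `examples/column.yaml`. Outputs:
`ccg_pairs.csv`, `tuning.csv`, `classes.csv`, `templates.csv`,
`evaluation.csv` and an aggregated `report.json`. Exit codes: 0 success,
2 config error, 3 data error.

## Acceptance

Property-based acceptance criteria (CCG hand fixtures, Poisson calibration,
jitter-null oracle equivalence, nuisance rejection, planted-parameter
recovery, clustering recovery, regression recovery, distance matching,
composition tests, CSD recovery, full-pipeline budget) live in
`tests/test_acceptance.py`. The report generator

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs a seeded end-to-end self-check and writes the (empty) numeric-target
report — there are no reproducible headline numbers for this package, since
the published values derive from raw recordings that require manual spike
sorting.
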