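simulate: true
data_dir: null
column:
  n_units: 120
  depth_range_um:
  - -700.0
  - 1000.0
  layer_boundaries_um:
    2/3:
    - 1000.0
    - 560.0
    4A/B:
    - 560.0
    - 360.0
    "4c\u03B1":
    - 360.0
    - 180.0
    "4c\u03B2":
    - 180.0
    - 0.0
    '5':
    - 0.0
    - -250.0
    '6':
    - -250.0
    - -700.0
  n_directions: 36
  n_repeats: 5
  trial_duration_s: 1.0
  stimulus_tf_hz: 4.0
  spatial_freq_cpd: 2.0
  bin_width_s: 0.001
  base_rate_mean_hz: 20.0
  base_rate_sd_hz: 5.0
  tuned_rate_mean_hz: 20.0
  kappa: 2.0
  preferred_scatter_deg: 15.0
  column_preferred_deg: 90.0
  fraction_simple: 0.3
  onset_amplitude_hz: 0.0
  onset_decay_s: 0.05
  slow_mod_amplitude: 0.0
  slow_mod_timescale_s: 0.1
  slow_mod_groups: []
  n_monosynaptic: 30
  mono_efficacy_p: 0.3
  mono_delay_range_ms:
  - 1.0
  - 4.0
  mono_jitter_sd_ms: 0.3
  n_common_input_groups: 10
  common_group_size: 2
  common_source_rate_hz: 20.0
  common_copy_p: 0.4
  common_jitter_sd_ms: 1.0
  distance_scale_um: 200.0
  tuning_similarity_weight: 1.0
  seed: 12
window:
- 0.4
- 1.0
bin_width_s: 0.001
min_rate_hz: 3.0
jitter_window_ms: 25.0
max_lag_ms: 100
threshold_sd: 7.0
peak_window_ms: 10.0
double_count_dist_um: 50.0
double_count_coincidence_ms: 0.167
double_count_frac: 0.2
exclude_flagged: true
cluster_seed: 0
cluster_tol: 0.02
perplexity: 30.0
sharp_width_ms: 4.0
force_k: null
mono_max_width_ms: 5.0
logistic_distance_range:
- 86.0
- 310.0
stats_seed: 0
seed: 12
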