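# Example run configuration for `ppglucose run-all --config config.example.yaml`.
# Every key is optional; omitted keys take the defaults shown here.
# Unknown keys are rejected.

seed: 42            # single global seed; per-stage substreams derive from it
out_dir: run_out    # where all artifacts and the manifest are written
# input_dir: cohort/   # read records from a cohort directory instead of simulating

# --- synthetic cohort -------------------------------------------------------
n_subjects: 80      # two records per subject (fasting + postprandial)
synth:
  # any SynthConfig field, e.g.:
  # fs_hz: 127.0
  # duration_s: 15.0
  # fasting_mean_mgdl: 93.0
  # fasting_sd_mgdl: 22.0
  # postprandial_mean_mgdl: 113.0
  # postprandial_sd_mgdl: 30.0
  # glucose_effect_sizes:            # glucose -> morphology slopes per mg/dL
  #   systolic_amplitude: 5.0e-3
  # noise:
  #   powerline_frequency_hz: 50.0   # set 60 for 60 Hz grids
  #   motion_artifact_rate_per_min: 2.0
  {}

# --- preprocessing ----------------------------------------------------------
filter:
  # order: 2
  # low_cut_hz: 0.5
  # high_cut_hz: 5.0
  # zero_phase: true
  {}

# --- segmentation / feature extraction --------------------------------------
segmentation:
  # min_period_s: 0.6
  # max_period_s: 1.0
  # min_prominence_fraction: 0.3
  # k_pulses: 3
  # per_pulse_stats: false
  # physical_units: false
  {}

# --- feature preparation ----------------------------------------------------
selection_threshold: 0.3   # |Pearson r| cutoff for the shortlist
feature_range: [0.0, 1.0]  # min-max scaling target range
iqr_factor: 1.5            # outlier fence width
glucose_range: [65.0, 160.0]

# --- modelling --------------------------------------------------------------
feature_mode: engineered   # engineered | selected | combined
algorithm: random_forest   # random_forest | svm | knn | gradient_boosted_trees
                           # | decision_tree | linear
hyperparameters: {}        # overrides for the chosen algorithm
train_fraction: 0.5
grouping: record           # record | subject (subject avoids pair leakage)
write_records: true        # write every per-record CSV (bulkiest artifact)

log_level: INFO
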