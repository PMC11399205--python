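# Full pipeline: synthetic development + external cohorts, 90th/95th
# percentile thresholds, 1000-replicate bootstrap CIs.
development:
  n_nodules: 883
  malignant_fraction: 0.07361268403171007
  cohort: development
external:
  n_nodules: 374
  malignant_fraction: 0.553475935828877
  cohort: external
  type_mix:
    0: [0.81, 0.05, 0.14]
    1: [0.90, 0.072, 0.028]
  size_distribution:
    0: {median_mm: 6.8, sigma: 0.58}
    1: {median_mm: 22.4, sigma: 0.65}
  difficulty_model:
    base: 0.18
percentiles: [90, 95]
subgroup_percentile: 90
bootstrap_reps: 1000
seed: 1
output_dir: uqtriage_run
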