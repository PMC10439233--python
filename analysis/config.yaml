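# Shared configuration for the numbered analysis drivers.
outdir: results/analysis
seed: 7
input_contours: null
n_per: 100
n_groups: 3
dtw_weights:
  time_weight: 10.0
  f0_weight: 3.513
  f0_change_weight: 2.413
  vibrato_weight: 1.973
dtw_resample_ms: 20.0
nmmds_restarts: 4
group_test_permutations: 999
vigilance: 96.0
art_resample_ms: 20.0
art_max_iterations: 50
n_trees: 300
train_frac: 0.67
cv_folds: 10
cv_repeats: 3
mtry_grid: [1, 2, 3, 4, 5, 6, 7]
diversity_bootstrap: 200
diversity_ci: 0.84
specificity_permutations: 1000
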