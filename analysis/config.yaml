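# Study configuration for the synthetic analysis: the default 200x200
# tropical world, 25 background draws, boosting trees capped at 1000.
outdir: results/run
base_seed: 7
B: 25
tau: 0.5
allowed_landcover: [6, 7, 8, 9, 10]
brt:
  learning_rate: 0.005
  tree_complexity: 4
  bag_fraction: 0.75
  n_folds: 10
  step_size: 50
  max_trees: 1000
synthetic:
  n_rows: 200
  n_cols: 200
  n_points: 1600
  n_climate: 8
  n_regions: 6
  seed: 7
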