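# Scaled-down end-to-end demonstration run (completes in a few minutes
# on one CPU).  Omitted keys take the package defaults.
out_dir: scratch/demo_run
simulate:
  grid: {n_rows: 80, n_cols: 80, cell_size: 50.0}
  n_sites: 3000
  cluster_count: 50
min_occurrence: 50
n_trees: 150
importance_permutations: 5
n_permutations: 10000
alpha: 0.05
grid_step: 100.0
cv_folds: 5
do_crossval: true
seed: 7
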