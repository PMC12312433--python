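# Full pipeline on a simulated study-conditions cohort.
# Replace `simulation` with `input: path/to/panel.csv` for real data
# (wide format: <node>_t1, <node>_t2, age, group columns).
simulation:
  preset: paper_like
covariates: [age]
group_col: group
estimation:
  n_folds: 10
  lambda_rule: min
imputation:
  n_trees: 100
  max_iter: 10
stability:
  enabled: true
  n_boot: 200
seed: 1
log_level: INFO
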