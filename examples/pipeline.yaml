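# Desk-scale end-to-end run on a generated synthetic cohort.
out_dir: runs/demo
seed: 7
cohort:
  n_cases_per_class: [20, 20, 20]
  roi_size: 96
normalization:
  lam: 0.1
  r: 2
cellularity:
  dilation_size: 11
classifier:
  epochs: 25
  input_size: 48
  folds: 5
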