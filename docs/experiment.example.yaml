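# Example experiment configuration for `radiosem run`.
# Omitted keys fall back to the package defaults (the full desk-scale
# study: 200 subjects, 30 s each, NORMAL/AF/PB in 2:1:1 proportion).
seed: 1
cohort:
  n_subjects: 50          # smoke-scale cohort
  duration_s: 30.0
  noise_sigma: 1.0
ecg:
  epochs: 200
radio:
  epochs: 120
protocol:
  k_folds: 7
rep_fraction: 0.6
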