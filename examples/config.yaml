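# Demo pipeline configuration; omitted keys keep their defaults.
seed: 1
simulate:
  n_subjects: 5
  duration: 300.0          # seconds per epoch in `run`
  breath_rate_mean: 50.0   # breaths/min
  cardiac_rate: 150.0      # bpm
  noise_sd: 0.05
breaths:
  alpha: 0.4               # threshold = alpha x SD of previous n_breaths
  n_breaths: 15
apnoea:
  ibi_threshold_s: 20.0
stats:
  pause_threshold_s: 5.0
  n_permutations: 10000
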