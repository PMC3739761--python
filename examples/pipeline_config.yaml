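# Full-pipeline configuration for `sciseq run-all --config ... --outdir ...`
# The simulation block mirrors the emulated study design; params override
# the module defaults.
simulation:
  n_genes: 2000
  stages: [CTR, D2, D7]
  replicates: [2, 3, 3]
  detection_limit: 0.1
  fraction_up: 0.05
  fraction_down: 0.05
  noise_sd: 0.25
  seed: 0
params:
  target_reliability: 0.99
  fc_cutoff: 2.0
  p_cutoff: 0.05
  top_fraction: 0.10
  k: 9
  fuzzifier: 1.25
  n_perm: 1000
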