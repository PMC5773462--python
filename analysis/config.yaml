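# Study configuration shared by the numbered analysis drivers.
# The synthetic cohort emulates the training/validation design:
# 71 training patients, 13 validation patients (one influential,
# below the training uptake minimum), a sparse planted signal in
# three sign-coherent co-expression modules, log2-SUV noise sd 0.4.
# Probe count is scaled to 4000 (signal 300) to keep a full run
# interactive; the generator accepts the full 22814 x 909 scale.
seed: 1
synthetic:
  n_probes: 4000
  n_samples: 71
  n_signal_probes: 300
  n_signal_blocks: 3
  block_rho: 0.7
  effect_size_range: [0.003, 0.0063]
  noise_sd: 0.4
  validation_n: 13
  include_influential: true
feature_selection:
  thresholds: [0.15, 0.25, 0.35]
  max_components: 3
  k: 10
models: [pls, pcr, svm, rf]
pls_components: 3
pcr_components: 18
cv:
  k: 10
  repeats: 5
cluster_k: 5
ssgsea:
  alpha: 0.25
  normalize: true
  n_sets: 20
  set_size_range: [10, 40]
heatmap: false
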