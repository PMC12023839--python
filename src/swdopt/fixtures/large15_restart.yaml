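# Complete 14-sequence, 15-period stepped wedge, one cluster per sequence,
# 50 participants per measured cluster-period; expensive intervention
# restart cost (equal to the per-cluster cost).
design:
  type: standard_sw
  n_sequences: 14
  clusters_per_sequence: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
  cluster_period_size: 50
correlation:
  structure: discrete_time_decay
  icc: 0.15
  cac: 0.8
costs:
  c: 2500
  k: 0
  kp: 0
  p: 80
  pp: 80
  g: 2500
  gp: 0
power:
  effect_size: 0.26
  alpha: 0.05
  min_power: 0.80
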