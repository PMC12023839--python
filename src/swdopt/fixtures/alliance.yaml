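# Complete 5-sequence, 6-period stepped wedge: 37 clusters (8,7,7,7,8),
# 7 participants per measured cluster-period. Costs in study currency.
design:
  type: standard_sw
  n_sequences: 5
  clusters_per_sequence: [8, 7, 7, 7, 8]
  cluster_period_size: 7
correlation:
  structure: discrete_time_decay
  icc: 0.05
  cac: 0.95
costs:
  c: 2500
  k: 0
  kp: 0
  p: 140
  pp: 80
  g: 230
  gp: 0
power:
  effect_size: 0.26
  alpha: 0.05
  min_power: 0.80
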