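# Full-scale interface width at t=1000, 30 replicates (NOT desk scale as a
# whole sweep, though a single replicate is fast).
kind: width
base:
  L: 300
  M: 1.0e-5
  T_max: 1000
sweep_variable: k
values: [0.5, 2.0, 5.0, 10.0, 15.0, 20.0]
replicates: 30
measurement: width_at_t
base_seed: 1
t_measure: 1000
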