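# Interface width at t=1000, reduced scale (about a minute).
kind: width
base:
  L: 102
  M: 1.0e-5
  T_max: 1000
sweep_variable: k
values: [0.5, 2.0, 10.0, 20.0]
replicates: 30
measurement: width_at_t
base_seed: 30007
t_measure: 1000
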