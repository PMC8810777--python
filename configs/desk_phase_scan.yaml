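# Coexistence-probability scan across the critical mobility (minutes).
kind: phase
base:
  L: 100
  M: 1.0e-5
  T_max: 10000
sweep_variable: M
values: [1.2e-4, 2.2e-4, 3.2e-4, 5.0e-4, 1.0e-3]
replicates: 24
measurement: phase_state
base_seed: 40009
t_measure: 10000
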