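# Full-scale matched-seed traditional-vs-territorial comparison, censored
# at 810,000 generations (NOT desk scale: days).
kind: traditional_vs_territorial
base:
  L: 300
  M: 1.0e-5
  T_max: 810000
sweep_variable: k
values: [2.0, 6.0, 10.0, 14.0, 18.0]
replicates: 30
measurement: extinction_time_low
base_seed: 1
censor_at: 810000
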