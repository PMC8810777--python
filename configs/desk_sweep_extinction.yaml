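# Reduced-scale low-mobility extinction sweep (minutes).
kind: extinction
base:
  L: 80
  M: 1.0e-5
  T_max: 30000
sweep_variable: k
values: [0.0, 5.0, 10.0, 20.0]
replicates: 30
measurement: extinction_time_low
base_seed: 20001
censor_at: 30000
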