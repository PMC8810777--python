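# Full-scale high-mobility density trajectory (NOT desk scale).
# Published protocol: 180,000 generations; plots use the first 140,000.
L: 300
M: 1.0e-3
k_A: 5.0
k_B: 5.0
k_C: 5.0
T_max: 180000
seed: 1
record_every: 100
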