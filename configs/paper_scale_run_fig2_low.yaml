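# Full-scale low-mobility density trajectory (NOT desk scale: hours).
# Published protocol: more than 490,000 generations; plots use the first
# 250,000.
L: 300
M: 1.0e-5
k_A: 5.0
k_B: 5.0
k_C: 5.0
T_max: 490000
seed: 1
record_every: 100
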