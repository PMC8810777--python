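# Single low-mobility run at desk scale (seconds-minutes).
L: 100
M: 1.0e-5
k_A: 5.0
k_B: 5.0
k_C: 5.0
T_max: 2000
seed: 1
record_every: 10
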