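# Wild-type MEF cell-cycle fixture: 20 hr cycle (G1 13 hr, S 4 hr, G2/M 3 hr).
name: wt_cc
g1: {family: lognormal, mean: 780.0, cv: 0.15}
s: {family: lognormal, mean: 240.0, cv: 0.15}
g2m: {family: lognormal, mean: 180.0, cv: 0.15}
growth: exponential
dna_noise_cv: 0.05
gate_halfwidth: 0.05
seed: 201
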