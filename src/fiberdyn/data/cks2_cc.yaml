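# Cks2-null cell-cycle fixture: total cycle 0.85x wild-type (17 hr), with a
# short G1 and long S so the S-phase occupancy is three times wild-type.
name: cks2_cc
g1: {family: lognormal, mean: 305.0, cv: 0.15}
s: {family: lognormal, mean: 535.0, cv: 0.15}
g2m: {family: lognormal, mean: 180.0, cv: 0.15}
growth: exponential
dna_noise_cv: 0.05
gate_halfwidth: 0.05
seed: 202
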