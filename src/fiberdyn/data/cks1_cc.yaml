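# Cks1-null cell-cycle fixture: total cycle ~3x wild-type (60 hr), slow S
# phase; S-phase occupancy about twice wild-type.
name: cks1_cc
g1: {family: lognormal, mean: 1937.0, cv: 0.15}
s: {family: lognormal, mean: 1423.0, cv: 0.15}
g2m: {family: lognormal, mean: 240.0, cv: 0.15}
growth: exponential
dna_noise_cv: 0.05
gate_halfwidth: 0.05
seed: 203
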