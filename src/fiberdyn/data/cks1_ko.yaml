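# Cks1-null MEFs: slow forks (1.4 kb/min); spacing as wild-type.
name: cks1_ko
region_length: 40000
n_molecules: 4
seed: 103
origin_spacing: {family: gamma, mean: 175.0, shape: 4.0}
firing_time: {family: uniform, low: -6.0, high: -3.0}
fork_velocity: {family: gamma, mean: 1.4, cv: 0.1}
sister_noise_sd: 0.03
stall_rate: 0.0002
pulses: {pulse1_label: IdU, pulse1_duration: 20.0, pulse2_label: CldU, pulse2_duration: 20.0, start_time: 0.0}
fiber_length: {family: lognormal, mean: 500.0, sigma_log: 0.5}
detection_limit: 1.0
kb_per_um: 2.0
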