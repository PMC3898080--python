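# Cks2-null MEFs after cyclin A knockdown: fork speed reduced to 1.57 kb/min.
name: cks2_ko_sicycA
region_length: 40000
n_molecules: 4
seed: 105
origin_spacing:
  family: mixture
  components:
    - {family: gamma, mean: 250.0, shape: 4.0}
    - {family: gamma, mean: 70.0, shape: 4.0}
  weights: [0.85, 0.15]
firing_time: {family: uniform, low: -6.0, high: -3.0}
fork_velocity: {family: gamma, mean: 1.57, cv: 0.1}
sister_noise_sd: 0.03
stall_rate: 0.0004
pulses: {pulse1_label: IdU, pulse1_duration: 20.0, pulse2_label: CldU, pulse2_duration: 20.0, start_time: 0.0}
fiber_length: {family: lognormal, mean: 500.0, sigma_log: 0.5}
detection_limit: 1.0
kb_per_um: 2.0
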