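I_A0: 1131.6
I_D0: 1500.0
background:
  acceptor: 20.0
  donor: 20.0
bleach_tau_A: 30.0
bleach_tau_D: 45.0
camera:
  excess_noise: 1.4142135623730951
  gain: 1.0
  offset: 0.0
  read_noise_sd: 3.0
comment: Acceptor-only calibration species for direct-excitation estimation
d_true: 0.05
exchange:
  k12: 0.0
  k21: 0.0
  mode: static
frame_time: 0.1
l_true: 0.1
n_cycles: 600
n_molecules: 200
shot_noise: true
species_fractions:
  acceptor_only: 1.0
  donor_only: 0.0
  double: 0.0
states:
- - 0.0
  - 1.0
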