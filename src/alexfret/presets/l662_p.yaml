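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
comment: 'L662 site, phosphorylated: unimodal population at E_PR 0.52'
d_true: 0.05
exchange:
  k12: 0.0
  k21: 0.0
  mode: static
frame_time: 0.1
l_true: 0.1
n_cycles: 600
n_molecules: 400
shot_noise: true
species_fractions:
  acceptor_only: 0.12
  donor_only: 0.18
  double: 0.7
states:
- - 0.52
  - 1.0
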