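label: aaf_terminal_ternary
description: 'Dpo4 ternary complex (with dATP) on the terminal AAF construct: major
  state close to 0.60 plus dynamic bursts to a small 0.87 peak.'
bound_states:
- name: B_main
  fret: 0.6
  weight: 0.8
  anchored: true
- name: B_burst
  fret: 0.87
  weight: 0.2
  anchored: true
k_off: 0.37
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
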