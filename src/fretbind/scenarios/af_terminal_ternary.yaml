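label: af_terminal_ternary
description: 'Dpo4 ternary complex (with dATP) on the terminal AF construct: single
  major state close to 0.60.'
bound_states:
- name: B_main
  fret: 0.6
  weight: 1.0
  anchored: true
k_off: 0.15
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
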