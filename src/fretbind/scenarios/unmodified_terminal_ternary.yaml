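label: unmodified_terminal_ternary
description: 'Dpo4 ternary complex (with dATP) on the unmodified terminal construct:
  single distribution at 0.57.'
bound_states:
- name: B_insertion
  fret: 0.57
  weight: 1.0
  anchored: true
k_off: 0.13
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
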