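label: unmodified_terminal_binary
description: 'Dpo4 binary complex with the primer terminus across from an unmodified
  G (terminal construct): states at 0.75 and 0.91.'
bound_states:
- name: B_low
  fret: 0.75
  weight: 0.5
  anchored: true
- name: B_high
  fret: 0.91
  weight: 0.5
  anchored: true
k_off: 0.52
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
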