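label: unmodified_ternary
description: 'Dpo4 ternary complex (with dCTP) on the unmodified templating-position
  construct: single insertion-complex distribution at 0.60.'
bound_states:
- name: B_insertion
  fret: 0.6
  weight: 1.0
  anchored: true
k_off: 0.13
k_off_anchored: true
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
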