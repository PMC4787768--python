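label: aaf_templating_ternary
description: 'Dpo4 ternary complex (with dCTP) on the AAF-modified templating-position
  construct: productive-like state at 0.63 with the 0.86 state retained.'
bound_states:
- name: B_main
  fret: 0.63
  weight: 0.7
  anchored: true
- name: B_high
  fret: 0.86
  weight: 0.3
  anchored: true
k_off: 0.37
k_off_anchored: true
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
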