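label: af_templating_ternary
description: 'Dpo4 ternary complex (with dCTP) on the AF-modified templating-position
  construct: predominant ternary state with a small higher-FRET shoulder.'
bound_states:
- name: B_main
  fret: 0.6
  weight: 0.7
  anchored: false
- name: B_shoulder
  fret: 0.72
  weight: 0.3
  anchored: false
k_off: 0.15
k_off_anchored: true
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
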