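label: af_templating_binary
description: 'Dpo4 binary complex with an AF-dG adduct at the templating base: predominant
  state 0.63 with a small overlapping shoulder at 0.42.'
bound_states:
- name: B_shoulder
  fret: 0.42
  weight: 0.3
  anchored: true
- name: B_main
  fret: 0.63
  weight: 0.7
  anchored: true
k_off: 0.37
k_off_anchored: true
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
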