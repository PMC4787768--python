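label: gg_mismatch_af_binary
description: Dpo4 binary complex, terminal G:G mismatch with AF-dG (nominal 0.50
  and 0.67).
bound_states:
- name: B_low
  fret: 0.5
  weight: 0.5
  anchored: false
- name: B_high
  fret: 0.67
  weight: 0.5
  anchored: false
k_off: 0.37
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
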