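label: ag_mismatch_af_binary
description: 'Dpo4 binary complex, terminal A:G mismatch with AF-dG: two peaks at
  about the terminal-AF positions, 0.50 and 0.67.'
bound_states:
- name: B_low
  fret: 0.5
  weight: 0.5
  anchored: true
- name: B_high
  fret: 0.67
  weight: 0.5
  anchored: true
k_off: 0.37
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
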