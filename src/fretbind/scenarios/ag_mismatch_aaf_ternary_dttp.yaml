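label: ag_mismatch_aaf_ternary_dttp
description: 'Dpo4 + dTTP on the AAF A:G-mismatch duplex: single lower population
  at 0.48 (dNTP-stabilized misalignment signature).'
bound_states:
- name: B_main
  fret: 0.48
  weight: 1.0
  anchored: true
k_off: 0.37
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
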