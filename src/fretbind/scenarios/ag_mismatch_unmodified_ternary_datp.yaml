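label: ag_mismatch_unmodified_ternary_datp
description: 'Dpo4 + dATP on the unmodified A:G-mismatch duplex: single population
  shifted low (nominal 0.56).'
bound_states:
- name: B_main
  fret: 0.56
  weight: 1.0
  anchored: false
k_off: 0.13
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
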