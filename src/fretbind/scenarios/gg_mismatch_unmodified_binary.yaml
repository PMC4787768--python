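label: gg_mismatch_unmodified_binary
description: Dpo4 binary complex on an unmodified duplex with a terminal G:G mismatch
  (nominal single population at 0.63).
bound_states:
- name: B_main
  fret: 0.63
  weight: 1.0
  anchored: false
k_off: 0.52
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
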