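label: unmodified_binary
description: 'Dpo4 binary complex on the unmodified templating-position construct:
  insertion (low-FRET) and preinsertion (high-FRET) conformations.'
bound_states:
- name: B_insertion
  fret: 0.57
  weight: 0.5
  anchored: true
- name: B_preinsertion
  fret: 0.8
  weight: 0.5
  anchored: true
k_off: 0.52
k_off_anchored: true
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
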