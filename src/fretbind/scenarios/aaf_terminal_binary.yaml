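label: aaf_terminal_binary
description: 'Dpo4 binary complex with a terminal AAF-dG adduct: markedly altered
  bimodal distribution (peak positions not printed; nominal values).'
bound_states:
- name: B_low
  fret: 0.6
  weight: 0.5
  anchored: false
- name: B_high
  fret: 0.84
  weight: 0.5
  anchored: false
k_off: 0.52
k_off_anchored: false
frame_interval: 0.08
max_duration: 60.0
n_molecules: 100
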