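seed: 7
shape: [41, 192, 192]
n_nuclei: 2
n_replicates: 2
deconvolve: true
conditions:
  - label: Hs68
    nucleus:
      telomere_length_dist: [5.3, 1.6, lognormal]
      min_separation: 1.0
      nucleus_semi_axes: [6.5, 4.5, 1.2]
  - label: Hs68_hTERT
    nucleus:
      telomere_length_dist: [18.9, 5.7, lognormal]
      min_separation: 1.0
      nucleus_semi_axes: [6.5, 4.5, 1.2]
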