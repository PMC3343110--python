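# Bundled toy run: simulate the default scenario (eight repeat elements, one
# ERVK internal element spiked +2 log2 in 3v3 arrays) and run every stage.
seed: 0
simulate: default
platform: generic
chemistry: probe_complementary_to_transcript
preprocess: log2_quantile
contrast: {case: case, control: control}
contrast_name: spiked_vs_control
parameters:
  fold_threshold: 2.0
  alpha: 0.01
groups:
  - {element: simERVK-A-int}
  - {repeat_class: LTR}
contigs:
  element: simERVK-A-int
  ltr: simLTR-A
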