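name: e13_5
mirror:
  rotations: [[1, 4.0], [2, 2.0]]
  mirror_fraction: 0.48
strip_non_cns: true
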