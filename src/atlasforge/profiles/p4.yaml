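name: p4
mirror:
  rotations: [[1, 0.22]]
  mirror_fraction: 0.487
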