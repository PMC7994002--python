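# Lateral-most labeled planes are incomplete; extension starts from the
# complete plane at 11%.
name: p28
extension:
  start_fraction: 0.11
mirror:
  rotations: [[1, 1.0]]
  mirror_fraction: 0.48
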