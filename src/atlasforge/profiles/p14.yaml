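# The lateral-most labeled plane is discontiguous and is skipped by the
# contiguous-stretch rule of find_extension_start.
name: p14
mirror:
  rotations: [[1, 0.4]]
  mirror_fraction: 0.50
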