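# A run of dorsoventrally compressed label planes is re-expanded to the
# histology bounding box before extension; extension starts at 13.7% along
# the sagittal axis where the basal ganglia begin tapering.
name: e18_5
expand_planes: [103, 108]
extension:
  start_fraction: 0.137
mirror:
  rotations: [[1, 1.5], [2, 2.0]]
  mirror_fraction: 0.525
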