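# Embryonic day 11.5 atlas. Labels already span the lateral extent, so no
# lateral extension; ventricles are labeled, so the edge map background uses
# the intensity threshold alone. The strongly skewed distal spinal cord needs
# piecewise affine shears whose ROIs are set per dataset at run time.
name: e11_5
do_extension: false
edge_map:
  background_strategy: threshold_only
mirror:
  rotations: [[1, 5.0], [2, 1.0]]   # 5 deg in axial planes, 1 deg in coronal planes
  mirror_fraction: 0.52
strip_non_cns: true
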