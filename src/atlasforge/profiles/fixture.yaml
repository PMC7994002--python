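# Profile matched to the synthetic phantom scale (128^3, ellipsoid-shell
# regions ~9 voxels thick). Structure-derived rules: edge-map sigma is about
# half the inter-boundary spacing so adjacent shell surfaces stay resolved;
# the seed erosion radius is about half a shell's half-width so every label
# keeps a core seed.
name: fixture
edge_map:
  gaussian_sigma: 2.0
extension:
  erosion_base: 3
refine:
  seed_erosion: 4
  skeleton_erosion: 2
  mask_opening: 0
  post_smooth:
    mode: adaptive_opening
    size: 1
smooth:
  mode: adaptive_opening
  size: 3
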