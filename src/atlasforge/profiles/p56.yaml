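# Bilateral labels; extension starts at 13.8%, mirroring at the true midline.
name: p56
extension:
  start_fraction: 0.138
mirror:
  mirror_fraction: 0.50
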