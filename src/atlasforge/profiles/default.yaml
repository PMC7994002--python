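# Default profile: sensible settings for the synthetic fixtures.
name: default
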