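Plant management option	p_low	p_high
no_removal	0.7	0.3
partial_removal	0.4	0.6
full_removal	0.1	0.9
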