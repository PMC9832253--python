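p_very_low	p_low	p_medium	p_high	p_very_high
0.2	0.2	0.2	0.2	0.2
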