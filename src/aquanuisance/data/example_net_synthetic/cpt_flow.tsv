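Ecosystem	Plant management option	p_low	p_high
lake	no_removal	0.95	0.05
lake	partial_removal	0.9	0.1
lake	full_removal	0.85	0.15
river	no_removal	0.5	0.5
river	partial_removal	0.3	0.7
river	full_removal	0.1	0.9
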