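Nutrient loading	Plant management option	p_low	p_high
low	no_removal	0.8	0.2
low	partial_removal	0.7	0.3
low	full_removal	0.6	0.4
high	no_removal	0.4	0.6
high	partial_removal	0.25	0.75
high	full_removal	0.1	0.9
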