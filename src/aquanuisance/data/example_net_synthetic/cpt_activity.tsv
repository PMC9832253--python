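p_swimming	p_boating	p_angling	p_biodiversity	p_landscape	p_birdwatching
0.1	0.25	0.25	0.15	0.2	0.05
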