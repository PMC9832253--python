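p_E. nuttallii	p_J. bulbosus	p_Ludwigia	p_P. crassipes	p_S. sagittifolia
0.2	0.2	0.2	0.2	0.2
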