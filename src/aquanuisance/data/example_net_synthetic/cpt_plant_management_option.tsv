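Perception	p_no_removal	p_partial_removal	p_full_removal
nuisance	0.15	0.35	0.5
no_nuisance	0.7	0.2	0.1
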