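Plant management option	p_weak	p_strong
no_removal	0.3	0.7
partial_removal	0.5	0.5
full_removal	0.75	0.25
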