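group	carriers	total
general population	152	4738
patient normal tissues	44	114
patient cancerous tissues	64	121
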