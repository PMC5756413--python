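source	label	target
F:A	is_a	F:R
F:A1	is_a	F:A
F:A2	is_a	F:A
F:B	is_a	F:R
F:B1	is_a	F:B
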