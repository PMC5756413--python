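format-version: 1.2
ontology: fig1-analogue

[Term]
id: EX:A
name: a
relationship: direct_part_of EX:B

[Term]
id: EX:B
name: b
relationship: direct_part_of EX:C

[Term]
id: EX:C
name: c

[Typedef]
id: direct_part_of
name: direct part of
is_a: part_of
is_transitive: true

[Typedef]
id: part_of
name: part of
is_transitive: true
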