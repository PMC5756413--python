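format-version: 1.2
ontology: background-example

[Term]
id: GO:0016049
name: cell growth

[Term]
id: GO:0048468
name: cell development

[Term]
id: GO:0048588
name: developmental cell growth
is_a: GO:0016049 ! cell growth
relationship: part_of GO:0048468 ! cell development

[Typedef]
id: part_of
name: part of
is_transitive: true
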