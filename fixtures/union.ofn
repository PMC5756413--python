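Prefix(:=<http://purl.obolibrary.org/obo/EX_>)
Ontology(<http://purl.obolibrary.org/obo/ex.owl>
Declaration(Class(:A))
Declaration(Class(:B))
Declaration(Class(:C))
Declaration(ObjectProperty(:R))
SubClassOf(ObjectUnionOf(:A :B) ObjectSomeValuesFrom(:R :C))
)
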