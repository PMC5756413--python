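!gaf-version: 2.1
! 10-entity annotation fixture over the F: toy graph (fixture_graph.tsv)
FB	E01	e01	 	F:A1	REF:1	IPI	FB:E02	P	entity one	 	protein	taxon:7227	20200101	FB
FB	E01	e01	NOT	F:B	REF:1	IDA	 	P	entity one	 	protein	taxon:7227	20200101	FB
FB	E02	e02	 	F:A1	REF:1	IDA	 	P	entity two	 	protein	taxon:7227	20200101	FB
FB	E03	e03	 	F:A2	REF:1	IGI	FB:E05|FB:E06	P	entity three	 	protein	taxon:7227	20200101	FB
FB	E04	e04	 	F:A	REF:1	IEA	 	P	entity four	 	protein	taxon:7227	20200101	FB
FB	E05	e05	 	F:B1	REF:1	IDA	 	P	entity five	 	protein	taxon:7227	20200101	FB
FB	E06	e06	 	F:B1	REF:1	IEA	 	P	entity six	 	protein	taxon:7227	20200101	FB
FB	E07	e07	 	F:B	REF:1	IGI	 	P	entity seven	 	protein	taxon:7227	20200101	FB
FB	E08	e08	 	F:A1	REF:1	IDA	 	P	entity eight	 	protein	taxon:7227	20200101	FB
FB	E08	e08	 	F:B1	REF:1	IEA	 	P	entity eight	 	protein	taxon:7227	20200101	FB
FB	E09	e09	 	F:A2	REF:1	IMP	 	P	entity nine	 	protein	taxon:7227	20200101	FB
FB	E09	e09	 	F:B	REF:1	IDA	 	P	entity nine	 	protein	taxon:7227	20200101	FB
FB	E10	e10	 	F:R	REF:1	IEA	 	P	entity ten	 	protein	taxon:7227	20200101	FB
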