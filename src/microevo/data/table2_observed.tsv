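# transcription of the published amino-acid auxotrophy evaluation (growth on
# defined medium lacking each amino acid; "+" = growth, "-" = auxotrophy)
#printed_total	m4_4=7	m2_6=11	p1_1_43=7
group	trait	m4_4	m2_6	p1_1_43	note
a-Keto-glutarate	E	-	-	-
a-Keto-glutarate	Q	+	+	+
Urea cycle	P	+	-	+
Urea cycle	R	-	-	-
3-P-glycerate	S	+	-	-
3-P-glycerate	G	+	+	+
3-P-glycerate	C	+	-	+
Oxalacetate	D	+	-	+
Oxalacetate	N	+	+	+
Oxalacetate	M	+	+	+
Oxalacetate	T	-	+	-
Oxalacetate	K	+	-	+
Pyruvate	A	+	+	+
Pyruvate	V	-	-	-
Pyruvate	I	-	-	-
Pyruvate	L	-	-	-
PEP-erythrose-4P	W	+	+	+
PEP-erythrose-4P	F	-	-	-
PEP-erythrose-4P	Y	+	+	+
Ribose-5P	H	+	+	+
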