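# transcription of the published phosphorus recycling/scavenging/storage
# gene repertoire; the alkaline-phosphatase row is a 3-level regulation state
# (Constitutive / Induce / -) and is excluded from binary concordance
group	trait	m4_4	m2_6	p1_1_43	note
Recycling	Alkaline phosphodiesterase I	+	+	+
Recycling	2',3' cyclic nucleotide transferase (yfkN)	+	+	+
Recycling	Alkaline phosphatase (phoA)	Constitutive	-	Induce	3-level
Scavenging	Phosphonoacetaldehyde dehydrogenase (phnY)	+	+	+
Scavenging	Phn transporters (phnCDE1E2)	-	+	-
Storage	Polyphosphate kinase ppK	+	+	+
Storage	Exopolyphosphatase	+	+	+
Storage	Teichoic acids biosynthesis genes	-	-	-
Storage	sqd1	+	+	+
Storage	sqdX	+	+	+
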