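# transcription of the published phosphorus-source utilization assays
group	trait	m4_4	m2_6	p1_1_43	note
Inorganic	Na2HPO3	-	-	-
Inorganic	KH2PO4	+	+	+
Inorganic	Ca3(PO4)2	-	-	+
Inorganic	X-P	-	-	-
Organic	DNA	+	+	+
Organic	RNA	-	-	-
Organic	2-AE-phosphonic acid	-	-	-
Organic	Phosphonoacetaldehyde	+	+	+
Organic	No phosphorus	-	-	-
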