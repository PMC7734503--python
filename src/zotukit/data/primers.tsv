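name	sequence	marker	direction	aliases
ITS1F	CTTGGTCATTTAGAGGAAGTAA	ITS1	forward	ITS1-F;ITS-1F
ITS5	GGAAGTAAAAGTCGTAACAAGG	ITS1	forward
ITS2	GCTGCGTTCTTCATCGATGC	ITS1	reverse	ITS-2
ITS3	GCATCGATGAAGAACGCAGC	ITS2	forward	ITS-3
ITS4	TCCTCCGCTTATTGATATGC	ITS2	reverse	ITS-4
fITS7	GTGARTCATCGAATCTTTG	ITS2	forward	fITS-7
gITS7	GTGARTCATCGARTCTTTG	ITS2	forward	gITS-7
ITS86F	GTGAATCATCGAATCTTTGAA	ITS2	forward	ITS86
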