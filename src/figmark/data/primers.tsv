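name	sequence	orientation	expected_length
AG-F	ATGKCGTWCCAAAACAAGGWGAWGA	forward	759
AG-R	TTASACTAATTGGAGGGCCATGGRA	reverse	759
AG-Marker-F	CAGGAGGAGGAAGCT	forward	146
AG-Marker-R	TTACACTAATTGGAGGGCCA	reverse	146
FcRAN1-F	ATGGCGGCGAGCGTCCGACA	forward	3015
FcRAN1-R	CTATTCTACAGTTATTTCTAGTATA	reverse	3015
RAN1-Marker-F	ATATCAAGAATGCAATCGAGGA	forward	608
RAN1-Marker-R	GCTGAGAAATAGACTAGAGATG	reverse	608
qPCR-F	CCACTGGCAAAGGCAATAGT	forward	156
qPCR-R	TTGAACTCCTCTGCCGGGAA	reverse	156
1-SNP-F	TCCTGTCTTTCTCATACGAGTAGTT	forward	371
1-SNP-R	TGGCGTCAGATGTTTTCCCC	reverse	371
6SNP-2-F	CTGGAGCTCTTCGTGCTTAC	forward	766
6SNP-2-R	AAGCATTGAACTCCTCTGCCG	reverse	766
2-SNP-F	TCACGATGTAAGGGCAGAGG	forward	444
2-SNP-R	GTGGTCAGCCTTGGTTTTCTG	reverse	444
Actin-F	GAACCACCAGACAGGACGATG	forward	250
Actin-R	CTACCACTGCTGAACGGGAAA	reverse	250
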