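patient	gene	exp_level	aa_change	classII_peptide	classII_ic50	classII_allele	classI_peptide	classI_ic50	classI_allele
BC1	NEK9	37	D542V	VQCGCVGTFLLTQSGKV	169	DRB1:0405	VQCGCVGTF	33	HLA-B15:01
BC1	SCML1	25	R199Q	TAKVLCYYIDQLKQGKCF	165	DRB1:0405	QLKQGKCF	151	HLA-B15:01
BC1	FGFR3	31	G380R	AGSVYAGILSYRVGFFLF	85	DRB1:0405	SYRVGFFLF	14	HLA-B24:02
BC1	RPS6KA3	47	P342L	FSTIDWNKLYRREIHLPF	52	DRB1:0405	KLYRREIHLPF	35	HLA-B15:01
BC1	ACTR3C	5	R32L	VLAKAASWTSRQVGELTL	124	DRB1:0901	RQVGELTL	169	HLA-B15:01
BC2	PREX1	49	H1429Y	VFYYIEGSRQALKVIFYL	17	DRB1:1201	VANTNVFYY	17	HLA-B35:01
BC2	LRBA	3	I1375R L1376R	VMDNMVMACGGRRPLLSA	35	DRB1:1201	MVMACGGRR	116	HLA-A11:01
BC2	FNDC3B	41	Y175C	QEIIPFCGMSTYITR	87	DRB1:1201	IPFCGMSTY	6	HLA-B35:01
BC3	NOTCH3	3895	N1588H	SVVMLEIDHRLCLQS	5	DRB1:0301	VMLEIDHRL	9	HLA-A02:01
BC3	KCTD6	279	S151F	TKVHFLLEGISNYFTKW	16	DRB1:1501	LTITTKVHF	23	HLA-B58:01
BC3	C1orf172	419	P203R				SLRSTFASSPR	43	HLA-A33:03
BC5	MRC2	386	R1437W	TAALILYWRRQSIER	3	DRB1:1201	TAALILYWR	12	HLA-A33:03
BC5	MERTK	30	S972L	RLVRNGVSWSHLSMLPLG	38	DRB1:1201	LVRNGVSWSHL	89	HLA-B07:02
BC5	SBNO2	12	V416M	VLDLQNKLPLARMVYASA	10	DRB1:1201	LPLARMVYASA	176	HLA-B07:02
BC5	TP53	29	Y126C	TCTCSPALNKMFCQLAKTCPV	57	DRB1:1201	TCTCSPAL	394	HLA-C03:03
BC5	FAM178A	1	P552R				RTKSPPAAL	107	HLA-B07:02
BC5	PDCL3	45	D67N	EENERAIEMYRRRRLAEW	68	DRB1:1454	EENERAIEMY	89	HLA-B44:03
BC5	TTN	3	A16911S	YQFRIFAENRYGQSFSL	285	DRB1:1454	AENRYGQSFSL	11	HLA-B40:01
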