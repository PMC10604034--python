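# Published gene annotation of the Psettodes belcheri mitogenome (GenBank OR231239, 16747 bp).
# Coordinates 1-based inclusive; intergenic value attached to the upstream gene row;
# the anticodon column prints codon-family triplets as in the deposited annotation.
gene	start	end	strand	size	intergenic	anticodon	start_codon	stop_codon
tRNA-Phe	1	69	H	69	0	TTC	.	.
12S rRNA	70	1030	H	961	0	.	.	.
tRNA-Val	1031	1102	H	72	26	GTA	.	.
16S rRNA	1129	2830	H	1702	0	.	.	.
tRNA-Leu	2831	2903	H	73	0	TTA	.	.
ND1	2904	3878	H	975	4	.	ATG	AGG
tRNA-Ile	3883	3952	H	70	1	ATC	.	.
tRNA-Gln	3954	4024	L	71	-1	CAA	.	.
tRNA-Met	4024	4093	H	70	0	ATG	.	.
ND2	4094	5138	H	1045	0	.	ATG	T--
tRNA-Trp	5139	5211	H	73	2	TGA	.	.
tRNA-Ala	5214	5282	L	69	1	GCA	.	.
tRNA-Asn	5284	5356	L	73	38	AAC	.	.
tRNA-Cys	5395	5460	L	66	0	TGC	.	.
tRNA-Tyr	5461	5530	L	70	1	TAC	.	.
COI	5532	7082	H	1551	0	.	GTG	TAA
tRNA-Ser	7083	7153	L	71	8	TCA	.	.
tRNA-Asp	7162	7230	H	69	8	GAC	.	.
COII	7239	7929	H	691	0	.	ATG	T--
tRNA-Lys	7930	8004	H	75	1	AAA	.	.
ATP8	8006	8170	H	165	-7	.	ATG	TAA
ATP6	8164	8844	H	681	2	.	ATG	TA-
COIII	8847	9629	H	783	2	.	ATG	TA-
tRNA-Gly	9632	9702	H	71	0	GGA	.	.
ND3	9703	10050	H	348	1	.	ATG	T--
tRNA-Arg	10052	10120	H	69	0	CGA	.	.
ND4L	10121	10414	H	294	-4	.	ATG	TAA
ND4	10411	11791	H	1381	0	.	ATG	T--
tRNA-His	11792	11859	H	68	0	CAC	.	.
tRNA-Ser	11860	11927	H	68	6	AGC	.	.
tRNA-Leu	11934	12006	H	73	0	CTA	.	.
ND5	12007	13845	H	1839	-1	.	ATG	TAA
ND6	13845	14363	L	519	0	.	ATG	TAG
tRNA-Glu	14364	14432	L	69	5	GAA	.	.
Cytb	14438	15578	H	1141	0	.	ATG	T--
tRNA-Thr	15579	15652	H	74	-1	ACA	.	.
tRNA-Pro	15652	15724	L	73	0	CCA	.	.
Control region	15725	16747	H	1023	.	.	.	.
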