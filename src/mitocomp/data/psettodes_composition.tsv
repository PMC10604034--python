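# Published partition-wise nucleotide composition of three Psettodes mitogenome
# records (P. belcheri OR231239; P. erumei FJ606835 and AP006835), as deposited.
# Percentages and skews as printed; skews recomputable from the percentage columns.
partition	accession	size_bp	pct_A	pct_T	pct_G	pct_C	pct_AT	at_skew	gc_skew
whole	OR231239	16747	28.09	26.06	16.24	29.56	54.15	0.037	-0.291
whole	FJ606835	17315	28.83	24.78	15.71	30.68	53.61	0.076	-0.323
whole	AP006835	16683	28.57	24.50	15.78	31.15	53.07	0.077	-0.328
PCGs	OR231239	11427	25.00	27.73	16.00	31.27	52.74	-0.052	-0.323
PCGs	FJ606835	11427	25.37	25.75	15.62	33.25	51.13	-0.008	-0.361
PCGs	AP006835	11426	25.33	25.62	15.62	33.43	50.95	-0.006	-0.363
rRNAs	OR231239	2689	31.42	21.38	21.87	25.33	52.81	0.190	-0.073
rRNAs	FJ606835	2680	32.43	20.56	20.86	26.16	52.99	0.224	-0.113
rRNAs	AP006835	2680	32.43	20.45	20.90	26.23	52.87	0.227	-0.113
tRNAs	OR231239	1556	27.83	27.31	23.14	21.72	55.14	0.009	0.032
tRNAs	FJ606835	1553	27.17	26.85	23.82	22.15	54.02	0.006	0.036
tRNAs	AP006835	1554	27.28	26.83	23.68	22.20	54.12	0.008	0.032
CR	OR231239	1015	30.25	33.40	12.51	23.84	63.65	-0.050	-0.312
CR	FJ606835	1601	38.91	33.92	10.31	16.86	72.83	0.069	-0.241
CR	AP006835	968	42.15	36.36	7.13	14.36	78.51	0.074	-0.337
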