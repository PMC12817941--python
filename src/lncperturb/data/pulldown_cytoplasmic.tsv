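# RNA pull-down mass-spectrometry peptide spectrum counts, cytoplasmic lysate.
# Columns: three sense-probe replicates (s1-s3), three antisense-probe replicates (a1-a3).
protein_id	mass_kda	s1	s2	s3	a1	a2	a3
IFIT3	56	4	7	4	0	0	0
LARS1	134	16	16	9	1	0	0
IFIT1	55	10	12	11	1	1	1
QARS1	88	15	14	14	2	1	2
AIMP1	34	8	9	5	1	0	1
MARS1	101	17	16	10	2	2	3
HNRNPK	51	22	22	17	5	5	3
RARS1	75	23	13	15	3	3	5
KARS1	68	48	35	45	12	9	9
PCBP2	39	4	3	4	0	1	0
FUBP1	68	31	38	37	12	10	11
IARS1	145	36	40	34	13	10	13
SART3	110	12	11	7	4	3	3
PUF60	60	16	22	20	7	6	10
U2AF2	54	13	11	11	6	6	2
DARS1	57	21	19	20	9	7	10
LRPPRC	158	138	141	141	68	62	55
EPRS1	171	35	35	18	12	14	13
SF3B3	136	8	11	7	3	4	5
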