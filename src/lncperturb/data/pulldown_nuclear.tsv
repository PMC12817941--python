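# RNA pull-down mass-spectrometry peptide spectrum counts, nuclear lysate.
# Columns: three sense-probe replicates (s1-s3), three antisense-probe replicates (a1-a3).
protein_id	mass_kda	s1	s2	s3	a1	a2	a3
LRPPRC	158	19	15	15	0	0	0
PCBP2	39	10	8	2	0	0	0
CSTF3	83	10	9	10	0	0	0
CELF1	52	11	9	7	0	0	0
CSTF2	61	6	5	5	0	0	0
TARDBP	45	6	5	3	0	0	0
CPSF7	52	5	4	4	0	0	0
FUBP1	68	24	24	23	5	2	2
KHSRP	73	87	91	84	15	12	9
FUBP3	62	8	7	5	0	0	1
ELAVL1	36	6	3	3	0	0	2
CSTF1	48	122	133	135	27	26	18
SYMPK	141	4	7	5	1	0	0
SF1	68	54	61	65	14	15	14
HNRNPM	78	20	23	19	6	5	4
PUF60	60	46	55	52	16	18	15
CPSF1	161	29	28	35	10	10	10
CPSF2	88	39	40	38	15	14	13
SCAF11	165	85	89	72	36	37	33
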