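regulator	module	assignment_score	n_genes	n_passengers	msigdb_categories	drug_target
STAT1	38	119.19	28	9	TF	0
BIRC5	16	109.21	38	14		0
TNFSF10	48	68.60	70	17	CDM,CGF	0
PML	85	67.12	31	10	O,TF,TCG	1
FGFR1	49	66.73	39	10	O,CDM,PK,TCG	1
BIRC5	49	65.83	39	10		0
DNMT3B	1	65.24	71	22		0
ERBB4	10	64.55	33	12	PK	1
RB1	55	64.22	37	11	TS,TF	0
AR	52	63.89	27	15	TF	1
PPARG	97	63.84	17	9	O,TF,TCG	1
BIRC5	102	56.81	174	20		0
BCL2	2	53.36	45	10	O,TCG	1
BCL2	40	52.92	68	10	O,TCG	1
IGFBP5	55	49.01	37	11		0
SOX7	6	44.23	43	18		0
AR	97	42.66	17	9	TF	1
PAX3	73	42.20	15	8	O,TF,HP,TCG	0
STAT1	72	39.37	17	8	TF	0
BIRC5	34	37.53	29	12		0
CUL3	95	31.17	14	7		0
RANBP3	11	30.11	45	15		0
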