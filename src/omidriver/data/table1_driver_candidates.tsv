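gene	chromosome	lr_cna	fc_ge	fc_me	fc_mirna	score
IL17RD	3	-0.33	-2.71	1.62	8.03	101.56
BCL2	18	-0.42	-2.70	1.45	7.53	96.73
IGFBP5	2	-0.35	-3.13	1.60	6.50	92.68
FOXP1	3	-0.51	-1.84	1.70	6.98	88.17
MTUS1	8	-0.39	-1.37	1.94	6.85	84.39
SOX7	8	-0.57	-1.14	1.97	6.64	82.52
AR	X	-0.35	-4.84	-1.38	8.01	79.20
MMP9	20	0.31	4.25	-1.44	-3.87	79.00
GNG7	19	-0.27	-2.30	1.53	5.66	78.00
SORCS3	10	-0.54	-4.27	-1.40	7.74	75.31
POLQ	3	0.73	3.01	0	-8.58	73.95
PPARG	3	-0.36	-3.58	1.40	3.49	70.65
ERBB4	2	-0.50	-3.23	0	7.96	70.11
MMP1	11	0.57	5.44	0	-5.56	69.39
SVIL	10	-0.44	-2.05	1.42	4.59	68.01
TACC1	8	-0.43	-2.87	0	7.69	65.98
SORBS1	10	-0.26	-5.06	0	5.58	65.38
OGG1	3	-0.38	-1.29	1.21	5.03	63.29
TFRC	3	1.40	2.31	0	-6.80	63.07
RFX2	19	-0.28	-2.45	1.71	3.44	63.00
CUL3	2	-0.50	-2.16	0	7.75	62.49
ZEB1	10	-0.46	-1.81	0	8.01	61.67
PML	15	0.39	1.43	0	-8.31	60.78
BIRC5	17	0.33	3.74	0	-5.94	60.07
ITPR1	3	-0.49	-2.57	0	6.72	58.69
CTDSP1	2	-0.49	-1.41	2.00	3.34	57.94
PAX3	2	-0.41	-3.39	-1.52	5.68	56.84
DNMT3B	20	0.39	1.39	0	-7.35	54.77
GSK3B	3	0.81	1.26	1.45	-6.99	54.38
RB1	13	0.97	0.92	2.12	-7.11	54.03
ARHGEF12	11	-0.63	-0.98	0	7.22	52.94
CADM1	11	-0.78	-2.27	-1.26	5.71	52.59
PPP2CB	8	-0.63	-0.86	1.40	3.68	52.50
STAT1	2	0.26	1.94	1.75	-6.53	52.39
LRIG1	3	-0.55	-1.92	0	6.25	52.31
FGFR2	10	-0.38	-1.05	1.37	3.73	52.24
TNFSF10	3	0.40	1.07	0	-7.23	52.23
ADAMTS9	3	-0.52	-1.89	-1.37	6.27	52.12
MKRN2	3	-0.45	-1.10	0	7.10	51.96
TGFBR2	3	-0.72	-1.31	0	6.62	51.88
ITGA9	3	-0.42	-2.52	0	5.70	51.80
FGFR1	8	-0.60	-3.08	0	4.91	51.54
RANBP3	19	-0.43	-0.92	1.43	3.63	51.34
MYOM2	8	-0.37	-1.82	1.48	2.74	51.26
CADM2	3	-0.42	-1.55	0	6.54	51.04
SERP1	3	0.42	1.22	1.63	-6.78	50.50
FNDC3B	3	0.63	1.20	1.34	-6.37	49.21
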