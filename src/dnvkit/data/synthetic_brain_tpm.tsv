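gene	cortex	frontal_cortex_ba9	cerebellum	hippocampus	caudate_basal_ganglia	putamen_basal_ganglia	cingulate_cortex	spinal_cord
ADAMTS16	2.85	2.16	17.83	1.98	17.83	14.39	2.4	1.23
ALPK3	4.41	13.92	3.03	1.68	0.65	13.92	2.57	4.97
ALS2CR12	6.77	23.9	0.9	0.5	23.9	3.41	1.34	4.84
ANKRD13B	12.07	3.76	3.09	3.15	7.53	7.87	12.07	1.35
BCL9L	7.45	4.25	5.79	7.45	3.65	6.24	1.83	1.24
BRD3	15.26	1.53	2.81	3.55	6.37	9.93	3.01	15.26
C2orf71	1.24	20.74	7.04	1.16	6.7	13.45	20.74	2.28
C9orf50	8.55	25.23	0.94	6.35	1.49	2.24	4.19	6.58
CACTIN	75.03	3.85	15.95	2.18	3.01	75.03	2.58	12.68
CEP55	12.19	5.1	10.6	28.09	28.09	12.7	5.53	8.42
COL21A1	3.29	11.46	3.16	15.2	13.35	3.33	18.33	18.33
CYP51A1	3.9	8.05	27.74	46.39	46.39	8.25	1.62	0.32
DSC2	3.87	4.08	3.51	3.76	9.68	3.24	9.68	7.88
FBXO42	2.01	5.91	3.87	4.2	2.83	5.91	0.75	0.87
FOLH1	22.71	1.46	0.63	11.31	1.04	1.66	4.08	26.65
INTS1	0.93	0.29	7.32	21.35	3.58	1.28	22.84	22.84
KAZN	1.16	0.58	3.14	2.76	2.92	4.34	26.18	3.49
KLHL29	8.71	3.2	1.66	41.71	8.26	6.24	41.71	5.13
KNSTRN	1.2	2.48	1.02	5.87	4.87	33.41	7.57	33.41
NUP133	26.12	5.2	6.65	6.36	10.96	6.58	3.45	1.66
OBSCN	5.97	12.62	11.43	6.01	14.69	14.69	7.37	8.17
PEX3	6.85	2.96	1.98	5.71	2.17	2.71	2.73	8.06
PNKD	8.68	4.33	22.83	5.16	5.68	22.83	1	7.41
PURG	2.34	3.82	5.03	4.26	9.14	9.14	5.69	7.5
RALGAPA2	25.56	1.59	5.65	24.65	7.25	5.25	25.56	3.26
SLC22A17	4.3	21.21	5.61	2.47	2.13	21.21	13.3	10.4
SPATA6	5.71	3.89	9.13	17.37	5.66	17.37	3.91	5.93
SRSF6	1.43	15.76	7.1	4.55	47.55	47.55	8.22	2.1
TIFAB	7.75	1.27	20.4	1.03	15.62	3.01	0.68	3.25
TNFRSF10A	2.17	2.02	2.2	11.13	4.19	2.45	0.55	4.39
VPS13B	19.41	2.3	3.32	0.87	5.92	1.14	19.41	3.13
ZFP57	5.22	3.42	1.78	5.58	3.72	5.96	1.31	5.96
ZNF469	17.3	0.1	17.3	4.27	5.72	4.21	7.24	1.89
ZNF669	0.67	15.21	5.14	0.83	4.97	1.09	15.21	4.39
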