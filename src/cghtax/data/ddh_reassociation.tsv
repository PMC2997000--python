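target_strain	intestinalis_DSMZ6629T_mean	intestinalis_DSMZ6629T_sd	johnsonii_ATCC33200T_mean	johnsonii_ATCC33200T_sd	crispatus_DSMZ20584T_mean	crispatus_DSMZ20584T_sd	gasseri_ATCC33323T_mean	gasseri_ATCC33323T_sd	acidophilus_CECT903T_mean	acidophilus_CECT903T_sd	taiwanensis_BL263_mean	taiwanensis_BL263_sd
murinus_BL262	1.95	1.39	3.68	2.29	2.41	0.83	4.82	2.47	1.23	0.07	15.22	4.65
reuteri_BL259	4.33	4.16	6.04	4.61	3.87	4.17	8.12	4.71	5.93	2.16	4.78	2.07
intestinalis_DSMZ6629T	100.00		6.00	1.26	3.66	1.10	4.08	0.86	6.79	2.11	3.52	1.05
intestinalis_BL260	107.55	4.18	9.90	3.70	7.75	4.33	9.93	4.83	9.77	0.23	7.27	1.86
johnsonii_ATCC33200T	7.74	1.49	100.00		5.15	0.70	19.32	1.51	7.57	1.73	20.76	1.32
johnsonii_CECT289	10.44	3.74	81.91	8.39	5.45	2.02	23.12	7.98	8.61	3.24	28.28	6.53
johnsonii_NCC2822	15.39	8.09	94.25	12.15	1.39	6.29	45.64	4.48	13.81	6.55	35.37	11.93
johnsonii_NCC1741	17.57	7.53	91.82	8.88	10.48	6.32	38.06	8.11	10.39	3.73	35.18	9.31
johnsonii_NCC533	9.70	5.52	76.78	8.09	9.73	7.20	24.53	8.96	8.31	3.82	24.94	8.71
johnsonii_NCC2767	16.00	7.28	106.05	7.91	13.33	8.54	45.02	14.95	11.35	3.62	39.75	11.45
johnsonii_BL261	7.07	3.58	56.49	8.70	6.04	2.44	19.74	3.73	12.02	10.84	24.15	2.27
crispatus_DSMZ20584T	7.34	2.86	6.22	1.06	100.00		4.28	2.06	11.70	5.35	4.20	1.90
crispatus_BL221	7.14	2.66	6.84	0.86	82.06	10.06	4.88	2.97	8.40	2.87	4.21	1.34
gasseri_ATCC33323T	3.99	1.88	15.62	2.19	3.63	1.61	100.00		3.25	0.77	9.89	2.56
gasseri_NCC2856	10.56	5.92	31.63	9.46	7.73	3.08	76.31	6.36	6.57	2.36	21.74	6.62
gasseri_NCC2857	11.54	6.36	41.76	12.27	11.11	6.48	79.66	15.14	8.73	3.21	25.55	8.95
gasseri_NCC2858	8.07	3.82	29.36	9.15	5.98	3.43	71.09	5.46	8.92	4.47	19.56	5.14
gasseri_BL223	5.06	2.07	21.28	1.75	4.21	1.38	62.11	9.80	3.29	0.88	14.13	2.67
acidophilus_CECT903T	8.28	2.65	7.06	0.08	9.84	3.14	6.18	2.42	100.00		4.74	0.80
acidophilus_CECT4529	8.59	3.38	6.79	1.73	9.08	3.40	3.68	0.61	98.60	6.52	3.96	1.23
acidophilus_CECT4179	7.10	3.61	5.12	1.50	6.72	2.72	3.39	1.61	101.10	2.45	3.96	0.64
taiwanensis_BL263	7.50	1.18	31.43	6.28	6.98	2.42	22.05	3.10	6.19	1.73	100.00
taiwanensis_BL301	3.55	0.51	18.20	5.85	3.82	0.34	12.61	2.42	3.26	0.66	72.61	10.45
taiwanensis_BL302	3.57	1.55	19.56	4.20	3.94	0.88	13.18	0.71	2.56	0.89	94.95	5.69
taiwanensis_BL303	3.55	0.29	17.65	6.63	3.74	1.00	12.96	2.37	3.23	0.05	86.54	8.38
taiwanensis_BL304	3.40	0.25	17.31	6.16	3.47	0.75	12.73	2.10	3.57	0.64	75.04	8.82
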