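family	transcript	comments	m_br	f_br	m_es	f_es	br_mean	es_mean	significant
Allatostatins	Unigene56418_All	A-type prepro-allatostatin, partial (N terminus)	34.32	35.6	16.05	13.42	34.96	14.74	1
Allatostatins	Unigene36127_All	A-type prepro-allatostatin, partial (middle)	34.14	35.77	11.78	13.75	34.96	12.77	1
Allatostatins	Unigene45628_All	A-type prepro-allatostatin, partial (C terminus)	32.56	38.8	13.85	13.49	35.68	13.67	1
Allatostatins	Unigene40422_All	B-type prepro-allatostatin, partial (N terminus)	39.12	40.22	52.4	60.14	39.67	56.27	1
Allatostatins	Unigene25318_All	B-type prepro-allatostatin, partial (C terminus)	46.66	54.5	57.75	64.03	50.58	60.89	0
Allatostatins	CL2090.Contig2_All	C-type prepro-allatostatin	11.08	11.04	3.22	3.42	11.06	3.32	1
Allatostatins	Unigene59348_All	Insects prohormone-1	527.56	565.95	379.48	353.88	546.76	366.68	1
Bursicon alpha subunit	CL593.Contig3_All	prepro-Bursicon alpha 2	2.07	2.06	0	0	2.07	0.00	1
Corazonin	Unigene32841_All	prepro-corazonin, partial	0.54	0	14.64	20.12	0.27	17.38	1
CCAP	Unigene1674_All	prepro-CCAP	30.9	28.86	81.84	54.44	29.88	68.14	1
CHH	CL7809.Contig1_All	prepro-CHH isoform B 1	0.12	0.46	309.12	450.84	0.29	379.98	1
CHH	CL7809.Contig3_All	prepro-CHH isoform B 2	0.04	0.19	127.88	238.64	0.12	183.26	1
CHH	CL7809.Contig4_All	prepro-CHH isoform B 3, partial (C terminus)	0.57	0.7	435.45	652.06	0.64	543.76	1
CHH	Unigene30324_All	prepro-CHH isoform B 4, partial (C terminus)	0	0	2.2	3.41	0.00	2.81	1
CHH	Unigene34312_All	prepro-CHH, unspecified	3.47	5.92	4.74	5.36	4.70	5.05	0
MIH/GIH	Unigene47171_All	prepro-MIH/GIH isoform A 1	0	0	2.51	4.65	0.00	3.58	1
MIH/GIH	Unigene60521_All	prepro-MIH/GIH isoform A 2	0	0.13	297.72	408.18	0.07	352.95	1
MIH/GIH	Unigene58466_All	prepro-MIH/GIH isoform A 3	0.05	0	4.41	8.33	0.03	6.37	1
CFSH	Unigene48118_All	prepro-CFSH	0	0	6.86	5.32	0.00	6.09	1
DH	CL8244.Contig2_All	prepro-DH class 2	78.61	70.11	66.36	61.51	74.36	63.94	0
Eclosion hormone	CL2590.Contig2_All	prepro-Eclosion hormone 1	3.9	3.01	49.2	29.2	3.46	39.20	1
Eclosion hormone	Unigene55076_All	prepro-Eclosion hormone 2	0	0	0	0.11	0.00	0.06	0
Myosuppressin	Unigene55051_All	prepro-FLP	56.18	65	58.99	48.62	60.59	53.81	0
Follistatin	CL3958.Contig2_All	Follistatin-like	0.18	0.29	0.06	0.06	0.24	0.06	0
Follistatin	Unigene49446	Follistatin-like, partial (N terminus)	0	0.06	0	0	0.03	0.00	0
Myostatin	CL113.Contig2_All	Myostatin	4.24	5.19	13.07	13.52	4.72	13.30	1
NPY	Unigene30121_All	prepro-NPF	3.08	2.91	47.64	46.86	3.00	47.25	1
Neuroparsin	Unigene5705_All	prepro-Neuroparsin	428.86	665.33	462.26	370.29	547.10	416.28	0
Neuroparsin	CL2744.Contig6_All	prepro-Neuroparsin 2	12.06	6.44	14.2	17.83	9.25	16.02	0
Orcokinin	Unigene692_All	prepro-Orcokinin	72.2	54.85	52.4	48.95	63.53	50.68	0
PDH	CL7594.Contig2_All	prepro-PDH	8.55	0.18	150.22	144.9	4.37	147.56	1
PDH	CL7594.Contig3_All	prepro-PDH	2.98	0.33	70.95	62.33	1.66	66.64	1
Prohormone-3	CL1958.Contig1_All	prohormone-3	44.39	23.14	60.68	60.61	33.77	60.65	1
Prohormone-4	Unigene19311_All	prohormone-4	51.09	34.79	28.36	19.2	42.94	23.78	1
RPCH	Unigene2547_All	prepro-RPCH	12.84	15.22	48.32	52.63	14.03	50.48	1
Sulfakinin	Unigene25008_All	prepro-Sulfakinin	9.88	0.66	4.7	3.01	5.27	3.86	0
Tachykinin	CL7656.Contig2_All	prepro-Tachykinin	365.98	457.61	100.12	88.78	411.80	94.45	1
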