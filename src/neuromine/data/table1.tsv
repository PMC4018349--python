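family	transcript	transcript_size_nt	orf_size_aa	comments	best_hit	evalue
Allatostatins	Unigene56418_All	955	248	A-type prepro-allatostatin, partial (N terminus)	allatostatin precursor protein [Panulirus interruptus] BAF64528	1.00E-115
Allatostatins	Unigene36127_All	462	154	A-type prepro-allatostatin, partial (middle)	allatostatin precursor protein [Panulirus interruptus] BAF64528	1.00E-64
Allatostatins	Unigene45628_All	1797	93	A-type prepro-allatostatin, partial (C terminus)	allatostatin precursor protein [Panulirus interruptus] BAF64528	6.00E-45
Allatostatins	Unigene40422_All	704	152	B-type prepro-allatostatin, partial (N terminus)	B-type preproallatostatin II [Pandalopsis japonica] AFV91539	4.00E-21
Allatostatins	Unigene25318_All	1537	135	B-type prepro-allatostatin, partial (C terminus)	B-type preproallatostatin II [Pandalopsis japonica] AFV91539	6.00E-44
Allatostatins	CL2090.Contig2_All	3784	141	C-type prepro-allatostatin	C-type preproallatostatin [Pandalopsis japonica] AFV91540	1.00E-33
Allatostatins	Unigene59348_All	1490	105	Insects prohormone-1	prohormone-1 [Apis mellifera] XP_001121443	5.00E-26
Bursicon alpha subunit	CL593.Contig3_All	1228	142	prepro-Bursicon alpha 2	bursicon [Procambarus clarkii] ADY80040	3.00E-79
Corazonin	Unigene32841_All	210	49	prepro-corazonin, partial	corazonin preprohormone [Daphnia pulex] ACJ05606	4.00E-06
CCAP	Unigene1674_All	1107	139	prepro-CCAP	crustacean cardioactive peptide [Homarus gammarus] ABB46292	4.00E-62
CHH	CL7809.Contig1_All	1021	135	prepro-CHH isoform B 1	prepro-crustacean hyperglycemic hormone isoform B [Nephrops norvegicus] AAQ22392	1.00E-60
CHH	CL7809.Contig3_All	1045	133	prepro-CHH isoform B 2	hyperglycemic hormone B [Homarus gammarus] ABA42180	8.00E-57
CHH	CL7809.Contig4_All	1576	112	prepro-CHH isoform B 3, partial (C terminus)	crustacean hyperglycemic hormone-like peptide precursor [Procambarus clarkii] ADZ98836	1.00E-40
CHH	Unigene30324_All	1453	126	prepro-CHH isoform B 4, partial (C terminus)	prepro-crustacean hyperglycemic hormone isoform B [Nephrops norvegicus] AAQ22392	8.00E-60
CHH	Unigene34312_All	1611	139	prepro-CHH, unspecified	hyperglycemic hormone [Pandalopsis japonica] AFG16932	5.00E-25
MIH/GIH	Unigene47171_All	679	115	prepro-MIH/GIH isoform A 1	prepro-gonad-inhibiting hormone isoform A [Macrobrachium nipponense] AEJ54622	4.00E-27
MIH/GIH	Unigene60521_All	1232	114	prepro-MIH/GIH isoform A 2	prepro-gonad-inhibiting hormone isoform A [Macrobrachium nipponense] AEJ54622	2.00E-26
MIH/GIH	Unigene58466_All	820	111	prepro-MIH/GIH isoform A 3	vitellogenesis inhibiting hormone [Homarus gammarus] ABA42181	3.00E-45
CFSH	Unigene48118_All	1067	278	prepro-CFSH	crustacean female sex hormonoe, partial [Carcinus maenas] AEI72264	2.00E-08
DH	CL8244.Contig2_All	1918	135	prepro-DH class 2	prepro-calcitonin-like diuretic hormone [Homarus americanus] ACX46386	2.00E-69
Eclosion hormone	CL2590.Contig2_All	1584	82	prepro-Eclosion hormone 1	eclosion hormone [Amphibalanus amphitrite] AFK81936	2.00E-14
Eclosion hormone	Unigene55076_All	757	86	prepro-Eclosion hormone 2	Eclosion hormone [Acromyrmex echinatior] EGI68318	4.00E-13
Myosuppressin	Unigene55051_All	819	100	prepro-FLP	prepro-myosuppressin [Homarus americanus] ACX46385	2.00E-40
Follistatin	CL3958.Contig2_All	686	133	Follistatin-like	follistatin-like, partial [Nematostella vectensis] ABF61774	2.00E-15
Follistatin	Unigene49446	708	204	Follistatin-like, partial (N terminus)	hypothetical protein DAPPUDRAFT_303124 [Daphnia pulex] EFX89772	3.00E-41
Myostatin	CL113.Contig2_All	1831	419	Myostatin	MSTN [Penaeus monodon] ADO34177	0
NPY	Unigene30121_All	1287	104	prepro-NPF	neuropeptide Y [Lymnaea stagnalis] CAB63265	3.00E-09
Neuroparsin	Unigene5705_All	1217	103	prepro-Neuroparsin	neuroparsin 1 precursor [Schistocerca gregaria] CAC38869	3.00E-12
Neuroparsin	CL2744.Contig6_All	1176	102	prepro-Neuroparsin 2	neuroparsin 1 precursor [Rhodnius prolixus] ACZ96369	7.00E-11
Orcokinin	Unigene692_All	1343	205	prepro-Orcokinin	prepro-orcokinin II [Homarus americanus] ACD13197	2.00E-104
PDH	CL7594.Contig2_All	430	79	prepro-PDH	pigment dispersing hormone related peptide precursor 79 - penaeid shrimp [Penaeus sp.] JC4756	2.00E-29
PDH	CL7594.Contig3_All	603	79	prepro-PDH	pigment dispersing hormone related peptide precursor 79 - penaeid shrimp [Penaeus sp.] JC4756	1.00E-23
Prohormone-3	CL1958.Contig1_All	2238	196	prohormone-3	prohormone-3 [Apis mellifera] XP_001122204	1.00E-44
Prohormone-4	Unigene19311_All	807	143	prohormone-4	prohormone-4-like [Acyrthosiphon pisum] XP_001951503	3.00E-86
RPCH	Unigene2547_All	1158	99	prepro-RPCH	red pigment concentrating hormone [Macrobrachium rosenbergii] ABV46765	2.00E-26
Sulfakinin	Unigene25008_All	902	115	prepro-Sulfakinin	preprosulfakinin [Homarus americanus] ABQ95346	7.00E-53
Tachykinin	CL7656.Contig2_All	2181	226	prepro-Tachykinin	preprotachykinin B [Panulirus interruptus] BAD06363	2.00E-143
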