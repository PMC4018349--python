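family	peptide	amidated	best_hit	accession	identity_note
Allatostatin A	HNNYAFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	TPDYAFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	EGMYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	DGMYSFGLa
Allatostatin A	ADLFSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	SGNYNFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	SQYAFGL	1	A-type allatostatin [Amphibalanus amphitrite]	AFK81929	100% identity
Allatostatin A	SKLYSFGL	1	FGLa-related allatostatin [Nilaparvata lugens]	BAO00953	QKLYSFGLa
Allatostatin A	NRQYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	SQQYAFGL	1	type-a prepro-allatostatin [Macrobrachium nipponense]	AEX86939	100% identity
Allatostatin A	PRNYAFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	PTAYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	PTTYSFGLa
Allatostatin A	TASYGFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	SDLYDNDLGRSYDFGL	0	allatostatin precursor protein [Panulirus interruptus]	BAF64528	SDSYDNGLGRRSYDFGL
Allatostatin A	SGPYAFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	GGPYAFGL	1	type-a pre-proallatostatin [Macrobrachium rosenbergii]	AAY82901	100% identity
Allatostatin A	ADLYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	ADPYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	AGQYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	AGPYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin A	EDSPASDAYTL	0	allatostatin precursor protein [Panulirus interruptus]	BAF64528	EDSSASDPYIL
Allatostatin A	SGSYSFGL	1	type-a prepro-allatostatin [Macrobrachium nipponense]	AEX86939	100% identity
Allatostatin A	AGPYSFGL	1	allatostatin precursor protein [Panulirus interruptus]	BAF64528	100% identity
Allatostatin B	TDWSSMHGTW	1	B-type preproallatostatin II [Pandalopsis japonica]	AFV91539	ADWSSMRGTWa
Allatostatin B	PDLLQAPLQAVGD	0	Na		
Allatostatin B	GNWDKFHGSW	1	B-type preproallatostatin II [Pandalopsis japonica]	AFV91539	ANWNKFQGSWa
Allatostatin B	AEEIQAAED	0	Na		
Allatostatin B	ADWNKFHGSW	1	Na		
Allatostatin B	GDEFASPELETTED	0	Na		
Allatostatin B	ANWNKFHGSW	1	B-type preproallatostatin II [Pandalopsis japonica]	AFV91539	ANWNKFQGSWa
Allatostatin B	GDDLVDAEL	0	Na		
Allatostatin B	DWSSLQGTW	1	B-type preproallatostatin I, partial [Pandalopsis japonica]	AFV91539	GWSSLQGSWa
Allatostatin B	DWNNLHGAW	1	B-type preproallatostatin I, partial [Pandalopsis japonica]	AFV91539	AWKNLHGAWa
Allatostatin B	SPDWNSLRGAW	1	B-type preproallatostatin I, partial [Pandalopsis japonica]	AFV91539	SGDWNSLRGAWa
Allatostatin B	APDWAQFRGSW	1	B-type preproallatostatin I, partial [Pandalopsis japonica]	AFV91539	DGDWSQFRGSWa
Allatostatin B	VPDEVNETAAHQA	0	Na		
Allatostatin C	ALGEEQLQEEAAKS	0	Na		
Allatostatin C	MFAPLSGLPGELPTI	0	C-type preproallatostatin [Pandalopsis japonica]	AFV91540	LFAPLSGLPGEIPTM
Allatostatin C	QIRYHQCYFNPISCF	0	C-type preproallatostatin [Pandalopsis japonica]	AFV91540	QIRYRQCYFNPISCF
Hormone-1	SYWKQCAFNAVSCF	1	prohormone-1 isoform X2 [Apis mellifera]	XP_006570429	100% identity
Corazonin	TFQYSRGWTN	1	Pro-corazonin [Harpegnathos saltator]	EFN88292	100% identity
Orcokinin	FDAFTTGFGHSKR	0	Orcokinin [Procambarus clarkii]	Q9NL83	100% identity
Orcokinin	NFDEIDRSGFAFAKK	0	Orcokinin [Procambarus clarkii]	Q9NL83	NFDEIDRSGFGFAKK
Orcokinin	NFDEIDRAGLGFAKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	NFDEIDRSGFGFNKR
Orcokinin	NFDEIDRSGFGFNKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	100% identity
Orcokinin	NFDEIDRAGLGFHKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	NFDEIDRSGFGFHKR
Orcokinin	NFDEIDRSGFGFNKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	100% identity
Orcokinin	NFDEIDRTGFGFHKR	0	Orcokinin [Procambarus clarkii]	Q9NL83	100% identity
Orcokinin	DYDGVYPDKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	DYD-VYPEKR
Orcokinin	NFDEIDRAGFGFVKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	NFDEIDRSGFGFVKR
Orcokinin	AFGPRDISNLYKR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	VYGPRDIANLYKR
Orcokinin	NFDEIDRSGFGFVRR	0	prepro-orcokinin II [Homarus americanus]	ACD13197	100% identity
PDH	NAELINSILGLPKVMNDA	1	Pigment-dispersing hormone [Uca pugilator]	P08871	NSELINSILGLPKVMNDAa
PDH	NAELINSLLGIPKVMSDA	1	Pigment-dispersing hormone [Litopenaeus vannamei]	P91963	NSELINSLLGIPKVMNDAa
Sulfakinin	EFDEYGHMRF	1	preprosulfakinin [Homarus americanus]	ABQ95346	100% identity
Sulfakinin	SGGEYDDYGHLRF	1	preprosulfakinin [Homarus americanus]	ABQ95346	GGGEYDDYGHLRFa
Tachykinin	APSGFLGMR	1	preprotachykinin [Procambarus clarkii]	BAC82426	100% identity
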