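patient_id	panel	phenotype	gene	hgvs	clinical_class
1	EP1.0V	malignant PGL	SDHB	SDHB(NM_003000.3):c.728G>A (p.Cys243Tyr)	pathogenic
2	EP1.0V	Pheo
3	EP1.0V	malignant PGL	SDHB	SDHB(NM_003000.3):c.586T>G (p.Cys196Gly)	pathogenic
4	EP1.0V	malignant PGL
5	EP1.0V	Pheo
6	EP1.0V	MEN2	RET	RET(NM_020975.6):c.1832G>A (p.Cys611Tyr)	pathogenic
7	EP1.0V	Pheo	TMEM127	TMEM127(NM_001193304.3):c.419G>A (p.Cys140Tyr)	likely_pathogenic
8	EP1.0V	Pheo
9	EP1.0V	malignant PGL	SDHB	SDHB(NM_003000.3):c.745T>C (p.Cys249Arg)	likely_pathogenic
10	EP1.0V	malignant PGL	SDHB	SDHB(NM_003000.3):c.649C>T (p.Arg217Cys)	likely_pathogenic
11	EP1.0V	malignant PGL	SDHB	SDHB(NM_003000.3):c.758G>A (p.Cys253Tyr)	pathogenic
12	EP1.0V	MEN2B	RET	RET(NM_020975.6):c.2753T>C (p.Met918Thr)	pathogenic
13	EP1.0V	Pheo	TMEM127	TMEM127(NM_001193304.3):c.320delG (p.Ser107Ilefs*17)	likely_pathogenic
14	EP1.0V	VHL	VHL	VHL(NM_000551.4):c.407T>G (p.Phe136Cys)	likely_pathogenic
15	EP1.0V	Pheo
16	EP1.0P	Pheo
17	EP1.0P	Pheo
18	EP1.0P	Pheo
19	EP1.0P	malignant PGL	SDHB	SDHB(NM_003000.3):c.286+2T>A	likely_pathogenic
20	EP1.0P	PGL
21	EP1.0P	NF1	NF1	NF1(NM_001042492.3):c.1756_1759delACTA (p.Thr586ValfsTer18)	pathogenic
22	EP1.0P	NF1	NF1	NF1(NM_001042492.2):c.5047_5053delinsGGAG (p.Asn1683_Ser1684_Trp1685delinsGlyGly)	vus
23	EP1.0P	NF1	NF1	NF1(NM_001042492.2):c.4230_4231delCC (p.Leu1411GlnfsTer12)	likely_pathogenic
24	EP1.0P	NF1	NF1	NF1(NM_001042492.2):c.1466A>G (p.Tyr489Cys)	pathogenic
25	EP1.0P	NF1	NF1	NF1(NM_001042492.2):c.2251+1G>A	likely_pathogenic
26	EP1.0P	NF1	NF1	NF1(NM_001042492.2):c.7465_7466insG (p.Lys2489ArgfsTer13)	likely_pathogenic
27	EP1.0P	Pheo
28	EP1.0P	NF1	NF1	NF1(NM_001042492.2):c.4175dupT (p.Val1393GlyfsTer2)	likely_pathogenic
29	EP1.0P	Pheo
30	EP1.0P	Pheo
31	EP1.0P	Pheo
32	EP1.0P	Pheo
33	EP1.0P	Pheo
34	EP1.0P	PGL-glomus caroticum	VHL	VHL(NM_000551.4):c.123_137dupAGAGTCCGGCCCGGA (p.Ser43_Glu47dup)	vus
35	EP1.0P	Pheo
36	EP1.0P	malignant PGL	SDHB	SDHB(NM_003000.3):c.263C>T (p.Thr88Ile)	vus
36	EP1.0P	malignant PGL	SDHB	SDHB(NM_003000.3):c.268C>G (p.Arg90Gly)	vus
36	EP1.0P	malignant PGL	SDHB	SDHB(NM_003000.3):c.271_273del (p.Arg91del)	likely_pathogenic
37	EP1.0P	Pheo
38	EP1.0P	Pheo
39	EP1.0P	Pheo
40	EP2.0	Pheo
41	EP2.0	Pheo	SDHB	SDHB(NM_003000.3):c.193C>T (p.Leu65Phe)	likely_pathogenic
42	EP2.0	Pheo
43	EP2.0	Pheo
44	EP2.0	Pheo
45	EP2.0	Pheo
46	EP2.0	Pheo
47	EP2.0	Pheo
48	EP2.0	Pheo	VHL	VHL(NM_000551.4):c.576delA (p.Asn193MetfsTer9)	likely_pathogenic
49	EP2.0	Pheo
50	EP2.0	Pheo&PGL	SDHB	SDHB(NM_003000.3):c.286+2T>A	likely_pathogenic
51	EP2.0	Pheo	FH	FH(NM_000143.4):c.1127A>C (p.Gln376Pro)	likely_pathogenic
52	EP2.0	Pheo
53	EP2.0	Pheo
54	EP2.0	abdominal PGL	SDHB	SDHB(NM_003000.3):c.689G>A (p.Arg230His)	pathogenic
55	EP2.0	Pheo
56	EP2.0	Pheo
57	EP2.0	malignant PGL
58	EP2.0	Pheo
59	EP2.0	Pheo
60	EP2.0	cervical PGL
61	EP2.0	NF1	NF1	NF1(NM_001042492.2):c.3456dupA (p.Leu1153ThrfsTer42)	pathogenic
62	EP2.0	Pheo
63	EP2.0	NF1	NF1	NF1(NM_001042492.2):c.888+2T>G	pathogenic
64	EP2.0	Pheo
65	EP2.0	Fumarase deficient leiomyoma	FH	FH(NM_000143.4):c.1256C>T (p.Ser419Leu)	likely_pathogenic
66	EP2.0	Pheo
67	EP2.0	Pheo	MDH2	MDH2(NM_005918.4):c.686G>A (p.Arg229Gln)	vus
68	EP2.0	Pheo	SDHA	SDHA(NM_004168.4):c.837G>T (p.Met279Ile)	vus
69	EP2.0	Pheo
70	EP2.0	Pheo
71	EP2.0	Pheo	RET	RET(NM_020975.6):c.2372A>T (p.Tyr791Phe)	vus
72	EP2.0	NF1	NF1	NF1(NM_001042492.2):c.6850_6853delACTT (p.Tyr2285fs)	pathogenic
72	EP2.0	NF1	SDHC	SDHC(NM_003001.5):c.94A>G (p.Thr32Ala)	vus
73	EP2.0	Pheo
74	EP2.0	Pheo
75	EP2.0	Pheo
76	EP2.0	NF1	NF1	NF1(NM_001042492.3):c.2991-1G>C	pathogenic
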