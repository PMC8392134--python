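sample_id	manifestations	age	benign_malignant	gene	hgvs	clinical_class
22	Neurofibromatosis Type 1: multiple neurofibromas; adrenal pheochromocytoma	30	B	NF1	NF1(NM_001042492.2):c.5047_5053delinsGGAG (p.Asn1683_Ser1684_Trp1685delinsGlyGly)	vus
23	Neurofibromatosis Type 1: multiple neurofibromas	32	B	NF1	NF1(NM_001042492.2):c.4230_4231delCC (p.Leu1411GlnfsTer12)	likely_pathogenic
26	Neurofibromatosis Type 1: adrenal pheochromocytoma	15	B	NF1	NF1(NM_001042492.2):c.7465_7466insG (p.Lys2489ArgfsTer13)	likely_pathogenic
28	Neurofibromatosis Type 1	26	B	NF1	NF1(NM_001042492.2):c.4175dupT (p.Val1393GlyfsTer2)	likely_pathogenic
36	Extra-adrenal PGL	14	M	SDHB	SDHB(NM_003000.3):c.263C>T (p.Thr88Ile)	vus
36	Extra-adrenal PGL	14	M	SDHB	SDHB(NM_003000.3):c.268C>G (p.Arg90Gly)	vus
36	Extra-adrenal PGL	14	M	SDHB	SDHB(NM_003000.3):c.271_273del (p.Arg91del)	likely_pathogenic
48	Adrenal pheochromocytoma	15	B	VHL	VHL(NM_000551.4):c.576delA (p.Asn193MetfsTer9)	likely_pathogenic
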