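name	abbrev	swissprot_id	pathways	phylo_class	hm_similarity
Glucokinase	GK	P35557	G	U	98.3
6-phosphofructokinase	F6P	P17858	G	U	97.0
fructose-bisphosphate aldolase (A)	FBa	P04075	G	U	98.9
fructose-bisphosphate aldolase (B)	FBb	P05062	G	U	99.7
fructose-bisphosphate aldolase (C)	FBc	P09972	G	U	98.6
glyceraldehyde 3-phosphate dehydrogenase	GAPD	P04406	G	U	97.0
bisphosphoglycerate phosphatase (1)	PGP1	P18669	G	U	99.6
bisphosphoglycerate phosphatase (2)	PGP2	P15259	G	U	95.2
Pyruvate kinase	PK	P30613	G	U	95.5
Lactate dehydrogenase A	LDHa	P00338	G	U	97.6
Lactate dehydrogenase B	LDHb	P07195	G	U	99.1
Pyruvate Dehydrogenase Complex A	PDCa	P08559	T	U	99.5
Pyruvate Dehydrogenase Complex B	PDCb	P11177	T	U	97.5
Pyruvate Dehydrogenase Complex C	PDCc	P29803	T	U	87.2
Citrate Synthase	CS	O75390	T,P	U	97.4
Aconitase	ACO	Q99798	T,P	U	98.8
Isocitrate Dehydrogenase (NAD+) (A)	IDHa	P50213	T,P	U	98.6
Isocitrate Dehydrogenase (NAD+) (G)	IDHg	P51553	T,P	U	97.2
Oxoglutarate Dehydrogenase Complex	OGDC	Q02218	T	U	94.1
Succinyl-CoA synthetase A	SCSa	P53597	T	U	97.0
Succinyl-CoA synthetase B	SCSb	Q96I99	T	U	96.1
Succinate Dehydrogenase A	SDHa	P31040	T	U	94.0
Succinate Dehydrogenase B	SDHb	P21912	T	U	97.0
Fumarase	FM	P07954	T,N	U	95.3
Malate Dehydrogenase (mitochondrion & cytosol)	MDH	P40926	T,N	U	97.6
Alanine Transaminase	AlaTA	P24298	N	U	92.5
Aspartate Transaminase	AspTA	P00505	N	U	98.4
Nucleoside Diphosphate Kinase	NDK	O00746	T	U	87.8
NADH: Ubiquinone oxidoreductase 1	MT-ND1	O15239	R	E	92.9
NADH: Ubiquinone oxidoreductase 2	MT-ND2	O43678	R	E	93.9
NADH: Ubiquinone oxidoreductase 3	MT-ND3	O95167	R	E	88.1
NADH: Ubiquinone oxidoreductase 4	MT-ND4	O00483	R	E	92.7
NADH: Ubiquinone oxidoreductase 5	MT-ND5	Q16718	R	U	91.3
NADH: Ubiquinone oxidoreductase 6	MT-ND6	P56556	R	U	90.8
NADH: Ubiquinone oxidoreductase 7	MT-ND7	O95182	R	E	95.5
NADH: Ubiquinone oxidoreductase 8	MT-ND8	P51970	R	U	94.7
NADH: Ubiquinone oxidoreductase 9	MT-ND9	Q16795	R	U	87.3
Ubiquinol: Cytochrome c Oxidoreductase H	UQCRH	P08574	R	U	92.3
Ubiquinol: Cytochrome c Oxidoreductase I	UQCRI	P47985	R	U	94.5
Ubiquinol: Cytochrome c Oxidoreductase Q	UQCRQ	O14949	R	E	85.2
Ubiquinol: Cytochrome c Oxidoreductase R1	UQCRR1	O14957	R	M	92.7
Ubiquinol: Cytochrome c Oxidoreductase C2	UQCRC2	P22695	R	U	93.2
Cytochrome c Oxidase 6B1	Cox6B1	P14854	R	E	96.5
Cytochrome c Oxidase 2	Cox2	P00403	R	U	86.8
Cytochrome c Oxidase 8a	Cox8a	P10176	R	V	85.5
Cytochrome c Oxidase 5A	Cox5a	P20674	R	U	88.0
Cytochrome c Oxidase 4A	Cox4a	P13073	R	E	89.9
Cytochrome c Oxidase 6C	Cox6c	P09669	R	M	86.7
Cytochrome c Oxidase 7B	Cox7b	P24311	R	V	88.8
Cytochrome c Oxidase 1	Cox1	P00395	R	U	95.5
Cytochrome c Oxidase 7R	Cox7r	O14548	R	E	93.0
Cytochrome c Oxidase 7C	Cox7c	P15954	R	E	88.9
Oxoglutarate Carrier	OGC	Q02978	N,P	E	97.8
Citrate Carrier	CIC	P53007	M	E	96.5
Nicotinamide nucleotide transhydrogenase	NNT	Q13423	S	U	96.2
Glutathione reductase	GSSGR	P00390	S	U	89.3
Glutathione peroxidase	GSSGP	P07203	S	U	90.6
Glycerol-3-phosphate dehydrogenase (FAD dependent)	GUT2P	P43304	N	U	97.0
Glycerol-3-phosphate dehydrogenase (NAD+)	G3PD	P21695	N	U	96.8
Malate Dehydrogenase (oxaloacetate-decarboxylating) (NADP+) X	MEx	P48163	P	U	94.9
Malate Dehydrogenase (oxaloacetate-decarboxylating) (NADP+) N	Men	Q16798	P	U	96.4
ATP/ADP Carrier 2	AAC	P05141	M	U	99.3
cytosolic Isocitrate Dehydrogenase (NADP+) P	IDHcp	P48735	P	U	82.0
cytosolic Isocitrate Dehydrogenase (NADP+) C	IDHcc	O75874	P	U	97.8
Pyruvate Carboxylase	PC	P11498	T,P	U	98.6
ETF:Q oxidoreductase	ETF-QO	Q16134	N	U	95.8
Manganese-dependent superoxide dismutase 2 C	SOD2c	P00441	S	U	88.9
Manganese-dependent superoxide dismutase 2 M	SOD2m	P04179	S	U	91.9
Manganese-dependent superoxide dismutase 2 E	SOD2e	P08294	S	U	75.2
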