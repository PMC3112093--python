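abbrev	omim_code	disease
GK	125851	MODY, type II
GK	125853	Insulin resistance, susceptibility to
GK	602485	Hyperinsulinemic hypoglycemia, familial, 3
GK	606176	Diabetes, permanent neonatal
FBa	229600	Fructose intolerance
FBc	611881	Glycogen storage disease XII
PGP2	261670	Glycogen storage disease X
PK	102900	Adenosine triphosphate, elevated, of erythrocytes
PK	266200	Pyruvate kinase deficiency
PDCa	308930	Leigh syndrome, X-linked
PDCa	312170	Pyruvate dehydrogenase deficiency
PDCb	312170	Pyruvate dehydrogenase deficiency
OGDC	203740	Alpha-ketoglutarate dehydrogenase deficiency
SCSa	245400	Lactic acidosis, fatal infantile
SDHa	115310	Paraganglioma, familial chromaffin, 4
SDHa	171300	Pheochromocytoma, modifier of
SDHa	606864	Paraganglioma and gastric stromal sarcoma
SDHa	612359	Cowden-like syndrome
SDHb	252011	Mitochondrial respiratory chain complex II deficiency
SDHb	256000	Leigh syndrome, due to Cox deficiency
FM	150800	Multiple cutaneous and uterine leiomyomata
FM	605839	Leiomyomatosis and renal cell cancer
FM	606812	Fumarase deficiency
MT-ND1	252010	Mitochondrial complex I deficiency
MT-ND2	256000	Leigh syndrome, due to Cox deficiency
UQCRQ	124000	Mitochondrial complex III deficiency
Cox6B1	220110	Mitochondrial complex IV deficiency
Cox2	220110	Mitochondrial complex IV deficiency
Cox1	220110	Mitochondrial complex IV deficiency
GUT2P	125853	Insulin resistance, susceptibility to
IDHcc	137800	Glioblastoma, susceptibility to
PC	266150	Pyruvate carboxylase deficiency
ETF-QO	231680	Glutaricaciduria, type IIC
SOD2c	105400	Amyotrophic lateral sclerosis, susceptibility to
SOD2m	612634	Microvascular complications of diabetes, susceptibility to
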