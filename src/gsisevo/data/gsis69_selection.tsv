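abbrev	taxon	age_mya
MT-ND4	Percomorpha	190
MT-ND6	Percomorpha	190
MT-ND6	Catarrhini	31
MT-ND8	Eutheria	102
MT-ND8	Tetrapoda	359
UQCRC2	Theria	166
UQCRC2	Tetrapoda	359
UQCRC2	Clupeocephala	320
Cox8a	Eutheria	102
Cox4a	Theria	166
Cox4a	Murinae	37
Cox4a	Clupeocephala	320
Cox4a	Euteleostomi	420
Cox7r	Catarrhini	31
CIC	Eutheria	102
ETF-QO	Percomorpha	190
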