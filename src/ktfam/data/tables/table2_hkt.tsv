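species	family	locus	name
Athaliana	HKT	AT4G10310	Ara-tha-HKT1;1
Osativa	HKT	LOC_Os04g51820	Ory-sat-HKT1;1
Osativa	HKT	LOC_Os02g07830	Ory-sat-HKT1;3
Osativa	HKT	LOC_Os04g51830	Ory-sat-HKT1;4
Osativa	HKT	LOC_Os01g20160	Ory-sat-HKT1;5
Osativa	HKT	LOC_Os06g48810	Ory-sat-HKT2;1
Osativa	HKT	LOC_Os01g34850	Ory-sat-HKT2;3
Osativa	HKT	LOC_Os06g48800	Ory-sat-HKT2;4
Ptrichocarpa	HKT	POPTR_0018s13210	Pop-tri-HKT1;1
Ppatens	HKT	Pp1s63_164V6	Phy-pat-HKT1
Smoellendorffii	HKT	PACid_15414191	Sel-moe-HKT1
Smoellendorffii	HKT	PACid_15414777	Sel-moe-HKT2
Smoellendorffii	HKT	PACid_15422070	Sel-moe-HKT3
Smoellendorffii	HKT	PACid_15420572	Sel-moe-HKT4
Smoellendorffii	HKT	PACid_15412354	Sel-moe-HKT5
Smoellendorffii	HKT	PACid_15412619	Sel-moe-HKT6
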