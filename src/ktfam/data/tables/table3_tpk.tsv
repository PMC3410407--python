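species	family	locus	name
Athaliana	TPK	AT5G55630	Ara-tha-TPK1
Athaliana	TPK	AT5G46370	Ara-tha-TPK2
Athaliana	TPK	AT4G18160	Ara-tha-TPK3
Athaliana	TPK	AT1G02510	Ara-tha-TPK4
Athaliana	TPK	AT4G01840	Ara-tha-TPK5
Athaliana	TPK	AT5G46360	Ara-tha-KCO3
Osativa	TPK	LOC_Os03g54100	Ory-sat-TPKa
Osativa	TPK	LOC_Os07g01810	Ory-sat-TPKb
Osativa	TPK	LOC_Os09g12790	Ory-sat-TPKc
Ptrichocarpa	TPK	POPTR_0001s34510	Pop-tri-TPK01
Ptrichocarpa	TPK	POPTR_0001s37550	Pop-tri-TPK02
Ptrichocarpa	TPK	POPTR_0002s06010	Pop-tri-TPK03
Ptrichocarpa	TPK	POPTR_0002s18870	Pop-tri-TPK04
Ptrichocarpa	TPK	POPTR_0005s22460	Pop-tri-TPK05
Ptrichocarpa	TPK	POPTR_0008s00520	Pop-tri-TPK06
Ptrichocarpa	TPK	POPTR_0008s00530	Pop-tri-TPK07
Ptrichocarpa	TPK	POPTR_0011s02810	Pop-tri-TPK08
Ptrichocarpa	TPK	POPTR_0014s10900	Pop-tri-TPK09
Ptrichocarpa	TPK	POPTR_0016s00890	Pop-tri-TPK10
Ppatens	TPK	Pp1s114_5V6	Phy-pat-TPK01
Ppatens	TPK	Pp1s334_27V6	Phy-pat-TPK02
Ppatens	TPK	Pp1s9_180V6	Phy-pat-TPK03
Smoellendorffii	TPK	PACid_15414254	Sel-moe-TPK1
Smoellendorffii	TPK	PACid_15420903	Sel-moe-TPK2
Smoellendorffii	TPK	PACid_15415112	Sel-moe-TPK3
Smoellendorffii	TPK	PACid_15420585	Sel-moe-TPK4
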