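species	family	locus	name
Athaliana	SHAKER	AT5G46240	Ara-tha-KAT1
Athaliana	SHAKER	AT4G18290	Ara-tha-KAT2
Athaliana	SHAKER	AT2G26650	Ara-tha-AKT1
Athaliana	SHAKER	AT4G32500	Ara-tha-AKT5
Athaliana	SHAKER	AT2G25600	Ara-tha-SPIK
Athaliana	SHAKER	AT4G22200	Ara-tha-AKT2
Athaliana	SHAKER	AT4G32650	Ara-tha-AtKC1
Athaliana	SHAKER	AT3G02850	Ara-tha-SKOR
Athaliana	SHAKER	AT5G37500	Ara-tha-GORK
Osativa	SHAKER	LOC_Os01g45990	Ory-sat-OsAKT1
Osativa	SHAKER	LOC_Os01g11250	Ory-sat-Kc01
Osativa	SHAKER	LOC_Os01g52070	Ory-sat-Kc02
Osativa	SHAKER	LOC_Os01g55200	Ory-sat-Kc03
Osativa	SHAKER	LOC_Os02g14840	Ory-sat-Kc04
Osativa	SHAKER	LOC_Os04g02720	Ory-sat-Kc05
Osativa	SHAKER	LOC_Os04g36740	Ory-sat-Kc06
Osativa	SHAKER	LOC_Os05g35410	Ory-sat-Kc07
Osativa	SHAKER	LOC_Os06g14030	Ory-sat-Kc08
Osativa	SHAKER	LOC_Os06g14310	Ory-sat-Kc09
Osativa	SHAKER	LOC_Os07g07910	Ory-sat-Kc10
Ptrichocarpa	SHAKER	POPTR_0003s01270	Pop-tri-Kc01
Ptrichocarpa	SHAKER	POPTR_0004s08170	Pop-tri-Kc02
Ptrichocarpa	SHAKER	POPTR_0004s13910	Pop-tri-Kc03
Ptrichocarpa	SHAKER	POPTR_0006s15950	Pop-tri-Kc04
Ptrichocarpa	SHAKER	POPTR_0006s26140	Pop-tri-Kc05
Ptrichocarpa	SHAKER	POPTR_0006s26600	Pop-tri-Kc06
Ptrichocarpa	SHAKER	POPTR_0012s04000	Pop-tri-Kc07
Ptrichocarpa	SHAKER	POPTR_0017s02430	Pop-tri-Kc08
Ptrichocarpa	SHAKER	POPTR_0018s00970	Pop-tri-Kc09
Ptrichocarpa	SHAKER	POPTR_0018s06510	Pop-tri-Kc10
Ptrichocarpa	SHAKER	POPTR_0242s00230	Pop-tri-Kc11
Ppatens	SHAKER	Pp1s283_74V6	Phy-pat-AKT1
Ppatens	SHAKER	Pp1s3_156V6	Phy-pat-AKT2
Ppatens	SHAKER	Pp1s22_165V6	Phy-pat-AKT3
Ppatens	SHAKER	Pp1s2_170V6	Phy-pat-AKT4
Smoellendorffii	SHAKER	453399	Sel-moe-SmORK
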