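species	family	locus	name
Athaliana	HAK	AT2G30070	Ara-tha-KUP/HAK/KT1
Athaliana	HAK	AT2G40540	Ara-tha-KUP/HAK/KT2
Athaliana	HAK	AT3G02050	Ara-tha-KUP3
Athaliana	HAK	AT4G23640	Ara-tha-KUP4
Athaliana	HAK	AT4G33530	Ara-tha-KUP/KT5
Athaliana	HAK	AT4G13420	Ara-tha-HAK5
Athaliana	HAK	AT1G70300	Ara-tha-KUP/HAK/KT6
Athaliana	HAK	AT5G09400	Ara-tha-KUP/HAK/KT7
Athaliana	HAK	AT5G14880	Ara-tha-KUP/HAK/KT8
Athaliana	HAK	AT4G19960	Ara-tha-KUP/HAK/KT9
Athaliana	HAK	AT1G31120	Ara-tha-KUP/HAK/KT10
Athaliana	HAK	AT2G35060	Ara-tha-KUP/HAK/KT11
Athaliana	HAK	AT1G60160	Ara-tha-KUP/HAK/KT12
Osativa	HAK	LOC_Os04g32920	Ory-sat-HAK1
Osativa	HAK	LOC_Os01g70940	Ory-sat-HAK2
Osativa	HAK	LOC_Os01g27170	Ory-sat-HAK3
Osativa	HAK	LOC_Os08g36340	Ory-sat-HAK4
Osativa	HAK	LOC_Os01g70490	Ory-sat-HAK5
Osativa	HAK	LOC_Os01g70660	Ory-sat-HAK6
Osativa	HAK	LOC_Os07g47350	Ory-sat-HAK7
Osativa	HAK	LOC_Os03g21890	Ory-sat-HAK8
Osativa	HAK	LOC_Os07g48130	Ory-sat-HAK9
Osativa	HAK	LOC_Os06g42030	Ory-sat-HAK10
Osativa	HAK	LOC_Os04g52390	Ory-sat-HAK11
Osativa	HAK	LOC_Os08g10550	Ory-sat-HAK12
Osativa	HAK	LOC_Os06g45940	Ory-sat-HAK13
Osativa	HAK	LOC_Os07g32530	Ory-sat-HAK14
Osativa	HAK	LOC_Os04g52120	Ory-sat-HAK15
Osativa	HAK	LOC_Os03g37840	Ory-sat-HAK16
Osativa	HAK	LOC_Os09g27580	Ory-sat-HAK17
Osativa	HAK	LOC_Os09g38960	Ory-sat-HAK18
Osativa	HAK	LOC_Os02g31910	Ory-sat-HAK19
Osativa	HAK	LOC_Os02g31940	Ory-sat-HAK20
Osativa	HAK	LOC_Os03g37930	Ory-sat-HAK21
Osativa	HAK	LOC_Os07g01214	Ory-sat-HAK22
Osativa	HAK	LOC_Os09g21000	Ory-sat-HAK23
Osativa	HAK	LOC_Os06g15910	Ory-sat-HAK24
Osativa	HAK	LOC_Os02g49760	Ory-sat-HAK25
Osativa	HAK	LOC_Os08g39950	Ory-sat-HAK26
Osativa	HAK	LOC_Os03g37830	Ory-sat-HAK27
Ptrichocarpa	HAK	POPTR_0001s00590	Pop-tri-HAK1
Ptrichocarpa	HAK	POPTR_0002s23850	Pop-tri-HAK2
Ptrichocarpa	HAK	POPTR_0010s10440	Pop-tri-HAK3
Ptrichocarpa	HAK	POPTR_0001s03680	Pop-tri-HAK4
Ptrichocarpa	HAK	POPTR_0003s01820	Pop-tri-HAK5
Ptrichocarpa	HAK	POPTR_0003s10910	Pop-tri-HAK6
Ptrichocarpa	HAK	POPTR_0014s14180	Pop-tri-HAK7
Ptrichocarpa	HAK	POPTR_0013s08110	Pop-tri-HAK8
Ptrichocarpa	HAK	POPTR_0015s05040	Pop-tri-HAK9
Ptrichocarpa	HAK	POPTR_0001s21310	Pop-tri-HAK10
Ptrichocarpa	HAK	POPTR_0003s10920	Pop-tri-HAK11
Ptrichocarpa	HAK	POPTR_0003s13370	Pop-tri-HAK12
Ptrichocarpa	HAK	POPTR_0008s14660	Pop-tri-HAK13
Ptrichocarpa	HAK	POPTR_0008s14670	Pop-tri-HAK14
Ptrichocarpa	HAK	POPTR_0014s12700	Pop-tri-HAK15
Ptrichocarpa	HAK	POPTR_0019s08430	Pop-tri-HAK16
Ptrichocarpa	HAK	POPTR_0003s14800	Pop-tri-HAK17
Ptrichocarpa	HAK	POPTR_0010s10450	Pop-tri-HAK18
Ptrichocarpa	HAK	POPTR_0001s00580	Pop-tri-HAK19
Ptrichocarpa	HAK	POPTR_0001s12790	Pop-tri-HAK20
Ptrichocarpa	HAK	POPTR_0008s14040	Pop-tri-HAK21
Ptrichocarpa	HAK	POPTR_0010s11100	Pop-tri-HAK22
Ppatens	HAK	Pp1s6_102V6	Phy-pat-HAK1
Ppatens	HAK	Pp1s118_70V6	Phy-pat-HAK2
Ppatens	HAK	Pp1s143_101V6	Phy-pat-HAK3
Ppatens	HAK	Pp1s96_141V6	Phy-pat-HAK4
Ppatens	HAK	Pp1s74_90V6	Phy-pat-HAK5
Ppatens	HAK	Pp1s29_214V6	Phy-pat-HAK6
Ppatens	HAK	Pp1s16_292V6	Phy-pat-HAK7
Ppatens	HAK	Pp1s244_62V6	Phy-pat-HAK8
Ppatens	HAK	Pp1s19_61V6	Phy-pat-HAK9
Ppatens	HAK	Pp1s251_25V6	Phy-pat-HAK10
Ppatens	HAK	Pp1s33_316V6	Phy-pat-HAK11
Ppatens	HAK	Pp1s165_138V6	Phy-pat-HAK12
Ppatens	HAK	Pp1s134_179V6	Phy-pat-HAK13
Ppatens	HAK	Pp1s166_51V6	Phy-pat-HAK14
Ppatens	HAK	Pp1s488_12V6	Phy-pat-HAK15
Ppatens	HAK	Pp1s25_346V6	Phy-pat-HAK16
Ppatens	HAK	Pp1s91_133V6	Phy-pat-HAK17
Ppatens	HAK	Pp1s201_129V6	Phy-pat-HAK18
Smoellendorffii	HAK	PACid_15405883	Sel-moe-HAK1
Smoellendorffii	HAK	PACid_15408107	Sel-moe-HAK2
Smoellendorffii	HAK	PACid_15409215	Sel-moe-HAK3
Smoellendorffii	HAK	PACid_15411376	Sel-moe-HAK4
Smoellendorffii	HAK	PACid_15411378	Sel-moe-HAK5
Smoellendorffii	HAK	PACid_15413823	Sel-moe-HAK6
Smoellendorffii	HAK	PACid_15413143	Sel-moe-HAK7
Smoellendorffii	HAK	PACid_15422615	Sel-moe-HAK8
Smoellendorffii	HAK	PACid_15403105	Sel-moe-HAK9
Smoellendorffii	HAK	PACid_15404811	Sel-moe-HAK10
Smoellendorffii	HAK	PACid_15410020	Sel-moe-HAK11
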