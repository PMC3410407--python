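species	family	locus	name
Ppatens	OTHER_VG	XP_001753265	Phy-pat-BK1
Ppatens	OTHER_VG	XP_001773545	Phy-pat-BK2
Smoellendorffii	OTHER_VG	PACid_15411641	Sel-moe-BK1
Smoellendorffii	OTHER_VG	PACid_15417632	Sel-moe-BK2
Creinhardtii	OTHER_VG	Cre01.g022150.t1.1	Chl-rei-Kc01
Creinhardtii	OTHER_VG	Cre07.g329882.t1.2	Chl-rei-Kc02
Creinhardtii	OTHER_VG	Cre07.g330400.t1.2	Chl-rei-Kc03
Creinhardtii	OTHER_VG	Cre10.g432550.t1.1	Chl-rei-Kc04
Creinhardtii	OTHER_VG	Cre13.g594050.t1.1	Chl-rei-Kc05
Creinhardtii	OTHER_VG	Cre13.g603750.t1.2	Chl-rei-Kc06
Creinhardtii	OTHER_VG	Cre43.g787450.t1.1	Chl-rei-Kc07
Creinhardtii	OTHER_VG	Cre02.g146300.t1.2	Chl-rei-Kc08
Creinhardtii	OTHER_VG	Cre12.g531950.t1.2	Chl-rei-Kc09
Creinhardtii	OTHER_VG	Cre02.g144950.t1.2	Chl-rei-Kc10
CoccomyxaC169	OTHER_VG	Genemark1.4196_g	Coccomy-Kc01
CoccomyxaC169	OTHER_VG	Genemark1.7704_g	Coccomy-Kc02
CoccomyxaC169	OTHER_VG	Genemark1.8069_g	Coccomy-Kc03
CoccomyxaC169	OTHER_VG	estExt_fgenesh1_pg.C_190110	Coccomy-Kc04
MicromonasRCC299	OTHER_VG	XP_002500200	Micromo-Kc01
MicromonasRCC299	OTHER_VG	XP_002508929	Micromo-Kc02
MicromonasRCC299	OTHER_VG	XP_002509136	Micromo-Kc03
MicromonasRCC299	OTHER_VG	XP_002500877	Micromo-Kc04
MicromonasRCC299	OTHER_VG	XP_002502332	Micromo-Kc05
MicromonasRCC299	OTHER_VG	XP_002500929	Micromo-Kc06
MicromonasRCC299	OTHER_VG	XM_002502171	Micromo-Kc07
MicromonasRCC299	OTHER_VG	XM_002504550	Micromo-Kc08
MicromonasRCC299	OTHER_VG	XM_002501933	Micromo-Kc09
Otauri	OTHER_VG	Ot13g00490	Ost-tau-Kc01
Otauri	OTHER_VG	Ot11g00900	Ost-tau-Kc02
Otauri	OTHER_VG	Ot13g00630	Ost-tau-Kc03
Otauri	OTHER_VG	Ot01g04220	Ost-tau-Kc04
Otauri	OTHER_VG	Ot01g00450	Ost-tau-Kc05
Vcarteri	OTHER_VG	PACid_17996094	Vol-car-Kc01
Vcarteri	OTHER_VG	PACid_18005696	Vol-car-Kc02
Vcarteri	OTHER_VG	PACid_17996282	Vol-car-Kc03
Vcarteri	OTHER_VG	PACid_18006137	Vol-car-Kc04
Vcarteri	OTHER_VG	PACid_18007561	Vol-car-Kc05
Vcarteri	OTHER_VG	PACid_18000814	Vol-car-Kc06
Vcarteri	OTHER_VG	PACid_18001906	Vol-car-Kc07
Vcarteri	OTHER_VG	PACid_18004030	Vol-car-Kc08
Vcarteri	OTHER_VG	PACid_18008362	Vol-car-Kc09
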