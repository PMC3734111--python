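gene_symbol	class_label	family_label
vha68-1	V-ATPase subunits	A
vha68-2	V-ATPase subunits	A
vha68-3	V-ATPase subunits	A
Vha55	V-ATPase subunits	B
vha44	V-ATPase subunits	C
vha36-1	V-ATPase subunits	D
Vha36-2	V-ATPase subunits	D
Vha36-3	V-ATPase subunits	D
vha26	V-ATPase subunits	E
vha14-1	V-ATPase subunits	F
Vha14-2	V-ATPase subunits	F
vha13	V-ATPase subunits	G
vhaSFD	V-ATPase subunits	H
vha100-1	V-ATPase subunits	a
vha100-2	V-ATPase subunits	a
Vha100-3	V-ATPase subunits	a
Vha100-4	V-ATPase subunits	a
Vha100-5	V-ATPase subunits	a
Vha16-1	V-ATPase subunits	c
Vha16-1	V-ATPase subunits	c
Vha16-2	V-ATPase subunits	c
vha16-3	V-ATPase subunits	c
Vha16-4	V-ATPase subunits	c
Vha16-5	V-ATPase subunits	c
vhaAC39-1	V-ATPase subunits	d
VhaAC39-2	V-ATPase subunits	d
VhaM9.7-1	V-ATPase subunits	e
vhaM9.7-2	V-ATPase subunits	e
vhaM9.7-3	V-ATPase subunits	e
VhaM9.7-4	V-ATPase subunits	e
VhaPPA1-1	V-ATPase subunits	c''
VhaPPA1-2	V-ATPase subunits	c''
VhaAC45	V-ATPase subunits	AC45
nhe1	CPA exchangers	
Nhe2	CPA exchangers	
Nhe3	CPA exchangers	
Nha1	CPA exchangers	
Nha2	CPA exchangers	
NKCC	Selected other exchangers and cotransports	
Ndae1-RA/B	Selected other exchangers and cotransports	
Ndae1-RC	Selected other exchangers and cotransports	
Nckx30C	Selected other exchangers and cotransports	
NaPi-T	Selected other exchangers and cotransports	
Ncc60/Hsp60B	Selected other exchangers and cotransports	
Prestin	Selected other exchangers and cotransports	
Atpalpha-RC	Na+,K+ ATPase subunits	
Atpalpha-RD	Na+,K+ ATPase subunits	
CG3701	Na+,K+ ATPase subunits	
Nervana	Na+,K+ ATPase subunits	
nervana2	Na+,K+ ATPase subunits	
nervana3	Na+,K+ ATPase subunits	
CG5250	Na+,K+ ATPase subunits	
Ir	K+ channels	
Irk2	K+ channels	
Irk3	K+ channels	
KCNQ	K+ channels	
CG10465	K+ channels	
CG1467	K+ channels	
Shaker-RA	K+ channels	
Shaker-RC	K+ channels	
Shaker-RD	K+ channels	
SK	K+ channels	
SK-RA	K+ channels	
SK-RC	K+ channels	
SK(CT36054)	K+ channels	
Shaw-RA	K+ channels	
Shaw-RB	K+ channels	
CG10830	K+ channels	
CG10440	K+ channels	
Ork1	K+ channels	
CG15654	K+ channels	
Ih	K+ channels	
Drip	Water channels	
CG4019	Water channels	
CG7777-RA	Water channels	
CG7777-RB	Water channels	
CG17662	Water channels	
aquaporin	Water channels	
ClC-a	Cl- channels	
ClC-a-RD	Cl- channels	
ClC-b	Cl- channels	
ClC-c	Cl- channels	
ClIC	Cl- channels	
CG11340	Cl- channels	
Best1	Cl- channels	
Best2	Cl- channels	
tweety-RB	Cl- channels	
tweety-RA	Cl- channels	
CAH1	Carbonic anhydrase	
CAH2	Carbonic anhydrase	
CG3669	Carbonic anhydrase	
CG3940	Carbonic anhydrase	
CG18673	Carbonic anhydrase	
CG6074	Carbonic anhydrase	
CG11284	Carbonic anhydrase	
CG18672	Carbonic anhydrase	
CG1402	Carbonic anhydrase	
CG5379	Carbonic anhydrase	
CG10899	Carbonic anhydrase	
CG32968	Carbonic anhydrase	
CG12309	Carbonic anhydrase	
CG9235	Carbonic anhydrase	
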