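probe_id	gene_symbol	adult_salivary_gland	larval_salivary_gland	adult_midgut	larval_midgut	adult_tubule	larval_tubule	adult_hindgut	larval_hindgut	brain	testis	whole_fly
vha68-1	vha68-1	218	22	73	73	137	39	349	230	2615	159	465
vha68-2	vha68-2	13958	4065	4665	5247	6242	4898	5496	5099	441	353	1905
vha68-3	vha68-3	10	4	2	6	3	1	3	1	1	1403	109
Vha55	Vha55	6275	2265	2366	3636	4016	2817	3011	3827	1856	227	1071
vha44	vha44	5309	1474	1738	1753	2131	2524	2902	3131	1023	111	619
vha36-1	vha36-1	6927	1937	2245	2287	3336	2417	3089	3154	1008	170	859
Vha36-2	Vha36-2	3	2	3	2	1	1	0	0	0	716	45
Vha36-3	Vha36-3	20	7	6	7	10	4	50	30	8	30	36
vha26	vha26	11317	3937	4330	4646	6448	3979	5075	5110	2409	777	1976
vha14-1	vha14-1	7440	2941	2857	3341	3210	3995	3850	3612	1657	326	989
Vha14-2	Vha14-2	7	1	2	2	2	2	2	1	3	245	23
vha13	vha13	11129	3385	3960	3763	4963	4227	4468	4000	2318	889	2247
vhaSFD	vhaSFD	5151	2232	2332	3306	3711	3002	3324	3995	1047	589	917
vha100-1	vha100-1	630	409	176	261	204	383	283	270	1039	156	242
vha100-2	vha100-2	6360	1616	1469	1655	3657	1758	3357	3184	87	83	662
Vha100-3	Vha100-3	9	7	1	2	4	3	1	2	4	493	47
Vha100-4	Vha100-4	15	8	725	1181	10	6	9	12	3	5	33
Vha100-5	Vha100-5	6	2	1519	2104	419	636	423	1316	4	13	180
Vha16-1#1	Vha16-1	4822	1952	3306	3163	3433	3409	3808	3350	1339	332	1308
Vha16-1#2	Vha16-1	13363	5816	4646	4686	5140	4660	5211	4353	2637	656	2224
Vha16-2	Vha16-2	3	2	1	2	3	3	1	2	2	178	12
vha16-3	vha16-3	6	5	2	4	3	3	3	2	2	212	19
Vha16-4	Vha16-4	13	9	7	6	5	4	9	4	7	130	13
Vha16-5	Vha16-5	13	8	8	2	7	5	4	4	3	318	33
vhaAC39-1	vhaAC39-1	4106	1209	2203	2275	2650	1964	2671	2904	1069	198	747
VhaAC39-2	VhaAC39-2	32	5	27	16	10	7	8	4	3	215	15
VhaM9.7-1	VhaM9.7-1	441	327	175	183	459	416	191	165	72	52	178
vhaM9.7-2	vhaM9.7-2	6816	2324	3437	3702	3706	3032	3451	3456	706	463	1158
vhaM9.7-3	vhaM9.7-3	15	9	5	14	3	2	12	6	1221	39	61
VhaM9.7-4	VhaM9.7-4	5	13	4	2	4	3	13	12	2	684	57
VhaPPA1-1	VhaPPA1-1	8288	3139	3673	3796	5532	4187	4577	4511	1603	493	1130
VhaPPA1-2	VhaPPA1-2	5	8	1	4	3	1	3	7	1	370	27
VhaAC45	VhaAC45	8824	2883	3584	3461	4606	3690	4122	3809	1495	319	1210
nhe1	nhe1	1001	1338	244	245	521	442	259	226	200	136	120
Nhe2	Nhe2	6	10	36	16	6	51	14	85	53	12	9
Nhe3	Nhe3	95	61	32	60	28	86	377	185	557	15	81
Nha1	Nha1	2106	57	288	374	155	38	3064	1157	8	12	99
Nha2	Nha2	187	34	18	20	874	376	1653	742	10	7	45
NKCC	NKCC	2805	626	98	150	62	9	3715	886	273	116	125
Ndae1-RA/B	Ndae1-RA/B	7	240	47	114	111	383	78	83	107	27	22
Ndae1-RC	Ndae1-RC	2	14	1	3	7	6	6	1	87	60	9
Nckx30C	Nckx30C	22	13	5	8	9	8	10	6	323	23	20
NaPi-T	NaPi-T	2	1	2	1	2613	1490	8	5	1	0	43
Ncc60/Hsp60B	Ncc60/Hsp60B	10	174	61	87	7	16	29	74	159	97	70
Prestin	Prestin	75	50	373	313	339	318	266	507	55	37	92
Atpalpha-RC	Atpalpha-RC	1193	479	707	265	5427	996	3624	1255	1673	113	683
Atpalpha-RD	Atpalpha-RD	195	88	81	72	314	191	812	281	2489	26	213
CG3701	CG3701	2	1	4	1	2	1	4	3	1	69	8
Nervana	Nervana	3561	694	1327	1498	4556	2272	2922	2277	69	92	1102
nervana2	nervana2	140	213	16	27	14	14	122	226	1779	114	193
nervana3	nervana3	23	6	172	47	11	2	3143	7	3653	22	389
CG5250	CG5250	14	2	9	11	3	2	2	5	4	256	19
Ir	Ir	7480	725	506	782	1099	844	83	302	32	6	201
Irk2	Irk2	235	66	117	23	805	13	4564	3856	981	19	157
Irk3	Irk3	8	2	4	7	4932	2898	48	4	328	0	115
KCNQ	KCNQ	67	62	269	121	245	180	170	832	139	10	37
CG10465	CG10465	442	494	392	354	705	610	458	478	500	410	463
CG1467	CG1467	271	226	247	245	421	359	203	239			275
Shaker-RA	Shaker-RA	11	25	2	3	4	2	27	10	777	3	5
Shaker-RC	Shaker-RC	19	2	4	6	3	5	24	12	74	1	5
Shaker-RD	Shaker-RD	11	7	2	1	4	5	12	7	777	1	16
SK	SK	1	0	1	0	0	1	0	0	0	1	0
SK-RA	SK-RA	28	24	46	3	6	7	9	7			6
SK-RC	SK-RC	41	37	11	10	7	4	68	27	700	8	34
SK(CT36054)	SK(CT36054)	2	2	1	1	1	1	1	1	26	1	0
Shaw-RA	Shaw-RA	12	20	37	47	12	13	20	19	164	13	18
Shaw-RB	Shaw-RB	16	3	37	28	6	10	38	30	102	154	24
CG10830	CG10830	7	181	35	19	3	5	45	26	1288	11	37
CG10440	CG10440	6	2	5	6	2	16	6	5	258	4	9
Ork1	Ork1	29	0	111	60	38	17	164	413	129	0	180
CG15654	CG15654	2	1	3	6	2	1	27	21	0	14	21
Ih	Ih	21	7	28	29	29	16	116	35	998	47	77
Drip	Drip	7135	495	352	280	589	1024	466	937	12	312	116
CG4019	CG4019	2145	100	808	493	674	1339	162	409	72	14	455
CG7777-RA	CG7777-RA	2488	247	731	310	1188	1785	570	1738	109	38	1025
CG7777-RB	CG7777-RB	15	4	8	23	6	7	5	9	1	1	116
CG17662	CG17662	13	6	10	211	5	5	9	8	4	6	3
aquaporin	aquaporin	18	3	44	9	14	4	233	73	6	141	276
ClC-a	ClC-a	43	24	36	31	16	20	12	19	15	7	12
ClC-a-RD	ClC-a-RD	818	88	125	261	1162	660	322	367	343	12	106
ClC-b	ClC-b	173	163	164	191	130	250	169	177	211	55	136
ClC-c	ClC-c	568	1056	292	703	1335	875	361	600	568	75	317
ClIC	ClIC	1165	610	1123	587	146	153	863	803	160	74	246
CG11340	CG11340	6	9	202	129	183	120	3	11	2	2	14
Best1	Best1	133	26	79	155	551	300	644	405	144	25	163
Best2	Best2	487	196	32	9	127	96	442	541	7	114	191
tweety-RB	tweety-RB	4	2	1	2	2	1	2	4	33	1	4
tweety-RA	tweety-RA	4	1	1	4	2	1	4	4	88	7	5
CAH1	CAH1	13574	1389	2982	2571	978	1082	2906	3961	1566	121	478
CAH2	CAH2	1061	39	625	129	516	3	118	1248	394	42	102
CG3669	CG3669	2	1	1	1	1	1	0	1	1	0	0
CG3940	CG3940	112	14	434	475	16	25	364	176	1329	16	193
CG18673	CG18673	13	9	4	11	182	20	34	2	4	243	21
CG6074	CG6074	4250	15	148	316	13	2	941	348	8	21	64
CG11284	CG11284	902	636	546	942	1303	994	585	498	292	33	492
CG18672	CG18672	5	0	1	5	2	1	0	0	0	3	16
CG1402	CG1402	14	3	3	7	5	3	2	7	114	2	4
CG5379	CG5379	8	3	1	1	14	0	1	2	23	6	5
CG10899	CG10899	12	4	2	5	4	5	4	4	4	26	4
CG32968	CG32968	4	28	8	9	7	2	8	14	16	1	30
CG12309	CG12309	5	4	5	4	3	4	1	5	1	1145	79
CG9235	CG9235	27	11	8	15	11	13	13	9	8	281	28
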