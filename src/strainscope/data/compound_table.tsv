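row	name	formula	mz_exp	dm_ppm	producers	best	group	nl	alt_tag	known
1	Bagremycin A	C15H14NO3+	256.0967	0.4	MM113,MM25,MM31,MM83,MM40,MM37,MM109	MM31	1	0	0	1
2	Bagremycin B	C17H14NO4+	298.1074	0.1	MM113,MM25,MM31,MM83,MM40,MM37,MM109	MM113	1	0	0	1
3	Bagremycin C	C20H20N2O6S+	417.1115	0.1	MM113,MM31,MM83,MM40,MM37,MM109	MM37	2	0	0	1
4	Bagremycin E	C15H12O3+	241.0859	0.3	MM113,MM83,MM40,MM37	MM83	1	0	0	1
5	Bagremycin G	C16H13NO4+	284.0915	0.8	MM113,MM31,MM83,MM40,MM37,MM109	MM113	1	0	0	1
6	Bagremycin H	C16H14O4+	271.0964	0.2	MM113,MM83	MM83	1	1	0	0
7	Bagremycin I	C16H11NO3+	266.0812	0.1	MM113,MM83,MM37,MM109	MM83	1	1	0	0
8	Bagremycin J	C15H12NO3S+	286.0531	0.4	MM83,MM37	MM37	1	1	0	0
9	Bagremycin C2	C11H8N2O6S+	315.0643	0.7	MM31,MM83,MM40,MM37	MM83	2	0	0	0
10	Bagremycin K	C21H18N2O6S+	427.0959	0.3	MM113,MM25,MM31,MM83,MM40,MM37	MM31	ND	0	0	0
11	Bagremycin L	C22H20N2O6S+	441.1118	0.5	MM113,MM83	MM83	ND	0	0	0
12	Bagrelactone A	C15H13NO4+	272.0922	0.2	MM113,MM31,MM83,MM40,MM37,MM109	MM109	3	0	0	1
13	Bagrelactone B	C17H13NO4+	296.0916	0.2	MM83,MM37,MM109,MM113	MM83	ND	0	1	0
14	Bagrelactone C	C16H15NO3+	270.1125	0.1	MM113,MM109	MM113|MM109	ND	0	1	0
15	Bagrelactone D	C16H15NO5+	302.1023	0.1	MM83,MM40	MM83	3	0	0	0
16	Bagrelactone E	C17H17NO5+	316.1179	0.3	MM37	MM37	3	0	0	0
17		C19H18NO6+	356.1127	0.5	MM37,MM109	MM109	3	0	0	0
18		C15H20NO6+	310.1285	0.1	MM25,MM83,MM37,MM109	MM37	3	0	0	0
19		C16H15N2O6+	331.0919	0.8	MM113,MM25,MM40	MM40	3	0	0	0
20		C17H16NO6+	330.0969	0.8	MM25,MM83,MM40,MM37,MM109	MM109	3	0	0	0
21		C13H16NO6+	282.0972	0.1	MM113,MM25,MM31,MM83,MM37,MM109	MM37	3	0	0	0
22		C16H21N2O3+	289.1546	0.3	MM109	MM109	1	1	0	0
23		C28H27N2O8S+	551.1484	0.3	MM83	MM83	2	0	0	0
24		C23H21N2O7S+	469.1066	0.4	MM113,MM83	MM113	ND	0	0	0
25		C24H23N2O8S+	499.1170	0.1	MM113,MM25,MM31,MM83,MM109	MM31	ND	0	0	0
26		C23H25N2O8S+	489.1328	0.3	MM113,MM31,MM83,MM40,MM109	MM83	2	0	0	0
27		C22H21N2O7S+	457.1063	0.2	MM113,MM31,MM83,MM40,MM37,MM109	MM83	ND	0	0	0
28		C23H23N2O8S+	487.1171	0.3	MM113,MM83	MM83	ND	0	0	0
29		C31H28N3O8S+	602.1587	0.7	MM25,MM31,MM37,MM109,MM113,MM83	MM31	2	0	0	0
30		C30H23N3O9S+	602.1231	0.6	MM113,MM83	MM83	ND	0	0	0
31		C30H25N3O10S+	620.1336	0.1	MM31,MM37,MM40,MM83,MM109,MM113	MM113	2	0	0	0
32		C38H32N3O10S+	722.1799	0.5	MM113,MM83	MM83	2	0	0	0
33		C38H30N3O9S+	704.1696	0.2	MM113,MM83	MM83	2	0	0	0
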