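	s0	s1	s2	s3	s4	s5
g000	5	10	9	25	14	13
g001	4	13	12	17	13	7
g002	26	34	28	35	11	7
g003	53	71	101	169	93	53
g004	3	8	2	9	3	2
g005	44	28	57	76	70	29
g006	179	221	142	641	209	159
g007	109	226	71	369	162	85
g008	5	3	2	5	13	3
g009	187	172	141	456	185	101
g010	76	72	61	90	66	34
g011	257	227	356	920	310	145
g012	32	70	36	101	21	14
g013	236	250	112	261	182	89
g014	27	21	29	36	34	5
g015	58	90	77	123	73	55
g016	188	312	204	539	377	109
g017	71	121	63	137	70	53
g018	155	153	195	418	255	88
g019	46	67	38	115	66	52
g020	49	68	28	141	52	30
g021	582	1223	634	1462	325	351
g022	101	160	124	208	88	76
g023	120	268	128	393	209	108
g024	345	430	401	623	261	280
g025	8	7	4	23	3	2
g026	119	155	108	156	123	106
g027	290	355	365	843	393	390
g028	59	83	49	130	38	31
g029	9	6	4	15	8	2
g030	31	34	29	97	52	18
g031	103	140	80	298	135	63
g032	10	9	5	9	17	9
g033	463	951	692	1570	461	397
g034	35	42	21	80	37	23
g035	4	10	8	8	6	7
g036	13	7	3	14	7	7
g037	22	30	8	49	28	19
g038	50	78	30	55	34	26
g039	10	25	11	21	21	15
g040	16	41	17	50	15	13
g041	281	131	100	300	160	93
g042	3	5	1	6	3	4
g043	8	22	21	51	28	12
g044	154	231	194	294	157	79
g045	608	679	546	480	496	351
g046	92	225	215	297	203	86
g047	131	143	41	228	103	81
g048	47	40	25	57	24	27
g049	17	15	11	32	23	11
g050	24	25	29	34	17	6
g051	45	29	27	91	29	14
g052	52	40	48	92	63	44
g053	29	30	37	102	100	24
g054	10	16	12	9	10	4
g055	127	100	98	231	84	56
g056	246	524	360	470	274	98
g057	9324	10040	3305	10917	6354	3434
g058	7	2	6	12	1	1
g059	14	32	13	34	20	16
g060	167	83	85	136	100	74
g061	115	150	60	124	78	45
g062	21	21	31	58	12	12
g063	2	6	0	1	7	0
g064	22	51	28	19	16	23
g065	36	52	28	135	42	47
g066	7	8	6	17	11	3
g067	207	193	151	246	251	109
g068	24	22	18	41	17	7
g069	104	97	62	177	59	15
g070	11	22	13	20	11	7
g071	33	86	63	144	78	15
g072	117	162	48	175	178	62
g073	73	128	43	156	50	26
g074	247	438	231	412	206	72
g075	59	59	25	72	76	27
g076	119	143	60	140	116	55
g077	203	297	117	445	251	120
g078	10	7	2	17	5	4
g079	187	248	113	263	180	81
g080	116	201	181	342	321	214
g081	6	7	5	21	15	5
g082	41	77	30	58	66	42
g083	62	48	34	115	53	21
g084	61	125	67	220	106	78
g085	29	58	12	53	49	26
g086	71	84	26	89	58	41
g087	4	8	5	14	5	2
g088	43	48	18	39	45	8
g089	156	79	83	291	199	83
g090	7	18	7	24	7	8
g091	85	155	39	268	79	53
g092	206	144	70	314	385	133
g093	1	0	2	0	3	0
g094	245	166	198	313	93	99
g095	1639	1632	1290	1979	2002	1190
g096	15	13	16	14	18	7
g097	564	292	323	565	436	106
g098	34	40	58	107	17	15
g099	19	55	19	33	28	17
g100	3	22	9	25	18	12
g101	118	169	94	213	47	51
g102	541	469	216	783	579	240
g103	221	184	131	482	171	108
g104	140	316	227	691	307	316
g105	38	28	10	70	19	7
g106	26	23	19	74	15	4
g107	51	53	34	87	33	25
g108	123	148	58	123	112	72
g109	10	25	4	19	41	28
g110	286	178	317	541	336	141
g111	52	71	38	194	69	34
g112	9	8	4	9	10	17
g113	51	109	77	125	116	72
g114	6	8	3	7	4	2
g115	276	191	200	434	127	71
g116	159	163	125	232	108	84
g117	64	148	93	137	75	54
g118	20	19	19	41	13	6
g119	47	53	18	55	22	8
g120	65	77	56	118	69	33
g121	24	35	19	52	11	15
g122	79	90	53	164	91	37
g123	177	206	117	202	93	56
g124	17	15	17	41	24	7
g125	354	700	570	1269	662	291
g126	643	631	489	1195	635	387
g127	66	53	85	98	65	50
g128	298	207	94	199	161	105
g129	3	3	3	15	3	4
g130	30	8	16	12	14	11
g131	34	42	19	92	29	21
g132	3396	2388	1774	2992	2436	1014
g133	157	176	213	466	245	94
g134	102	104	119	232	107	70
g135	3	13	8	13	11	4
g136	30	31	24	51	17	18
g137	231	136	68	343	137	90
g138	65	49	53	103	35	24
g139	27	23	25	57	27	33
g140	179	225	141	221	130	54
g141	105	83	71	186	129	73
g142	260	305	119	600	223	205
g143	17	21	16	29	27	5
g144	336	759	261	829	137	134
g145	1573	3404	1862	3287	2204	1283
g146	3	5	6	20	16	5
g147	62	42	47	149	49	24
g148	3	6	1	10	4	0
g149	8	13	13	22	8	7
g150	77	154	93	180	43	13
g151	34	113	42	109	47	47
g152	0	5	0	3	2	1
g153	248	608	234	279	263	283
g154	159	102	74	337	181	88
g155	56	57	52	83	57	10
g156	31	31	30	41	29	2
g157	3	17	6	18	7	8
g158	60	94	105	143	140	75
g159	22	48	39	56	27	15
g160	14	12	9	19	6	8
g161	174	113	79	166	96	47
g162	102	268	101	214	61	50
g163	18	31	15	55	10	10
g164	215	450	335	601	260	377
g165	18	71	33	87	23	18
g166	385	422	305	788	193	183
g167	8	8	5	11	5	6
g168	475	1111	655	2216	567	512
g169	95	165	90	168	97	73
g170	6	6	1	11	10	0
g171	25	46	36	86	50	23
g172	118	59	82	231	142	62
g173	82	117	94	110	168	47
g174	2	0	1	1	1	0
g175	151	194	95	255	158	106
g176	13	5	2	15	5	2
g177	77	199	110	343	150	49
g178	11	12	13	26	11	7
g179	7	9	1	9	6	2
g180	57	104	41	101	51	72
g181	31	26	9	40	11	4
g182	56	46	49	55	39	41
g183	77	33	22	70	91	38
g184	15	6	10	19	13	7
g185	202	270	259	283	208	166
g186	81	76	20	228	197	36
g187	138	303	64	232	113	80
g188	5	9	5	17	3	3
g189	184	260	207	388	249	71
g190	514	599	362	1006	370	396
g191	83	147	93	307	72	47
g192	543	411	573	1055	548	167
g193	540	454	494	1066	407	245
g194	89	113	34	237	27	44
g195	16	24	10	55	21	7
g196	38	16	15	54	30	26
g197	409	700	351	1319	275	314
g198	109	168	138	244	172	53
g199	93	131	62	248	158	83
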