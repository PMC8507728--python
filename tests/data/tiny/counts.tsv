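genus_id	P000_T	P000_VN	P000_S	P001_T	P001_VN	P001_S	P002_T	P002_VN	P002_S	P003_T	P003_VN	P003_S	P004_T	P004_VN	P004_S	P005_T	P005_VN	P005_S	P006_T	P006_VN	P006_S	P007_T	P007_VN	P007_S	P008_T	P008_VN	P008_S	P009_T	P009_VN	P009_S	P010_T	P010_VN	P010_S	P011_T	P011_VN	P011_S
g0000	60	1108	1	17	14	5	20	90	36	225	74	57	107	49	1	39	143	15	73	175	8	411	743	148	44	395	1	182	128	53	42	27	11	46	74	0
g0001	34	278	2	47	21	2	10	86	8	170	15	9	25	24	0	148	34	27	126	194	11	36	98	20	341	87	1	59	9	76	3	78	12	2	24	1
g0002	356	8369	29	467	915	204	101	217	6	5489	845	94	317	59	6	294	456	65	185	278	54	442	1080	60	419	430	46	2011	428	234	83	448	417	177	526	2
g0003	4269	2838	77	23612	36798	1134	1069	9741	294	17299	5220	643	6483	1896	873	8943	5085	566	10978	10683	593	6470	9568	2719	12286	18319	170	927	12684	363	756	33736	241	5460	3453	195
g0004	454	1078	62	90	148	72	35	1443	22	353	163	396	866	62	66	89	33	52	1980	387	118	3914	145	388	829	3394	14	9465	27	105	157	581	71	781	784	37
g0005	135	5897	9	739	99	52	361	1494	37	1507	248	436	293	7187	5	359	2387	129	581	912	193	222	2066	1526	2868	1603	37	270	125	9	304	460	32	197	515	414
g0006	20	67	2	196	2	13	17	370	42	16	4	8	7	27	114	77	1	3	12	11	11	2907	80	46	278	0	1	1952	13	144	50	39	46	290	3	12
g0007	43	899	8	832	28	170	13	193	74	801	27	149	348	147	107	503	1246	569	841	358	24	4692	592	511	683	302	4	2385	31	841	245	26	185	7134	384	66
g0008	89	137	0	542	1	34	126	2	7	557	12	116	52	6	2	1761	3	21	429	19	52	110	20	32	95	26	1	11	8	22	873	17	1	55	9	4
g0009	11	18	0	260	5	75	675	22	5	49	8	68	19	18	10	602	4	0	36	10	2	19	82	27	2935	33	8	10	6	14	409	3	46	3	18	3
g0010	80	80	1	3	0	12	137	32	1	4775	3	10	429	50	20	8	4	1	4737	25	15	42	18	42	33	22	0	102	2	8	7	27	4	25	5	0
g0011	3142	1911	10	107	5	19	6979	98	29	2165	72	171	7055	19	23	39	8	22	5007	23	157	55	192	130	127	262	3	83	19	318	100	137	80	85	132	58
g0012	4	1061	1884	18	28	314	2	495	38	12	87	137	1	30	194	2	1	150	0	47	712	12	66	4181	8	184	98	2	4	295	0	88	511	33	97	778
g0013	28	1716	694	23	26	6346	78	1402	3699	509	365	7609	12	191	1212	22	274	7709	43	672	10019	77	663	12757	42	2308	2404	13	14	4197	34	144	511	96	1311	10306
g0014	0	101	13	2	1	656	5	55	22	47	17	171	1	67	206	1	25	3434	10	91	731	0	290	1825	13	126	44	0	58	495	0	7	75	3	57	194
g0015	12	1051	73	7	15	1148	29	90	102	100	10	946	6	43	335	8	29	730	27	57	2627	0	16	794	12	17	17	4	57	1119	29	232	1070	21	34	205
g0016	31	2073	2527	3	139	2224	100	2374	2316	780	215	4152	30	784	5901	186	290	6283	63	969	3153	64	1220	3887	148	910	235	68	584	8465	60	274	1847	181	1533	2251
g0017	73	3698	4440	23	52	5943	23	740	2648	36	272	4998	134	4832	2845	17	63	2432	175	653	2398	103	1580	8402	109	2909	13654	8	1748	2336	24	238	775	45	2040	1539
g0018	107	1058	51	141	249	109	740	979	1958	916	264	270	857	596	594	193	318	257	590	275	94	241	262	1071	133	333	17	674	41	767	1463	286	1395	1766	670	480
g0019	13	273	77	14	4	70	7	209	28	466	58	213	197	124	19	149	56	56	3293	1322	167	74	281	1394	199	358	3	76	4	196	75	474	197	47	149	57
g0020	2158	7908	22	252	45	446	133	493	494	669	174	269	55	4007	49	563	93	724	919	768	4376	274	558	1098	483	565	100	1128	160	380	178	1515	70	71	4784	6
g0021	357	7239	100	86	120	2038	532	574	379	1450	4713	372	80	326	384	224	54	1104	246	218	980	127	507	3277	420	1655	147	419	1457	508	64	212	142	81	96	11
g0022	77	3042	82	476	186	2049	734	3279	1854	894	1514	3388	466	3810	143	215	542	118	1587	718	5334	3113	916	643	347	4573	111	470	240	1355	2260	1089	1133	1502	385	293
g0023	108	4148	19	113	14	319	34	469	138	97	200	38	133	109	21	136	34	617	324	368	192	87	1686	359	57	15	16	1175	80	151	36	125	346	72	1319	14
g0024	6	248	44	59	56	172	40	262	40	549	44	167	59	139	43	704	65	31	376	442	107	175	590	366	413	101	9	45	15	15	18	44	554	74	340	41
g0025	0	105	22	0	0	12	2	1	0	1	5	10	5	3	0	2	0	6	19	19	28	4	21	10	0	6	3	4	2	8	2	15	3	125	7	9
g0026	8	978	10	67	20	117	84	46	15	44	80	82	152	45	71	122	103	142	206	170	30	13	431	171	69	316	0	9	10	147	14	8	118	54	13	17
g0027	16	450	7	4	2	11	19	38	6	20	59	27	39	12	4	3	4	27	59	14	22	13	67	13	45	445	6	17	21	114	32	13	8	124	173	104
g0028	21	686	15	40	5	39	7	56	2	42	14	74	11	35	13	31	299	12	293	176	110	100	122	198	89	47	6	15	101	211	17	64	239	22	79	67
g0029	31	1289	5	20	3	8	10	42	9	37	12	2	9	49	14	7	12	2	8	57	17	24	244	332	14	89	2	10	2	15	2	8	9	1	75	5
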