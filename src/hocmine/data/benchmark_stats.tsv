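code	annotated	classified	features	precision	recall	f1	accuracy
1	993	811719	7479	36.5	67.1	47.3	91.5
1.1	320	141941	3631	48.5	60.3	53.8	98.1
1.2	323	224980	3407	27.0	35.3	30.6	97.0
1.2.1	138	69880	1952	41.2	29.0	34.0	99.1
1.3	345	278561	3558	33.3	54.5	41.4	96.9
2	366	579810	4237	39.0	62.0	47.9	97.2
2.1	251	144562	2908	32.9	49.4	39.5	97.8
2.1.1	238	139071	2747	33.6	46.6	39.1	98.0
2.2	118	273566	1864	68.5	83.1	75.1	99.6
3	832	863918	7141	56.5	82.1	66.9	96.1
3.1	610	594979	5841	60.7	79.8	69.0	97.5
3.2	157	33845	1098	61.4	79.0	69.1	99.4
3.3	108	198429	1682	66.9	76.9	71.6	99.6
4	295	49223	2323	59.0	85.8	69.9	98.8
4.1	111	6407	1193	61.7	73.9	67.2	99.5
4.2	185	39298	1620	62.8	85.9	72.6	99.3
5	358	308574	2854	40.2	66.2	50.0	97.3
5.1	350	287854	2776	40.3	65.4	49.9	97.4
5.1.1	171	118377	1696	42.5	53.2	47.3	98.8
6	667	943054	5218	54.5	75.9	63.4	96.7
6.1	282	271211	3202	50.1	62.4	55.6	98.4
6.2	317	591214	3383	53.8	71.3	61.3	98.4
7	768	1397318	5675	36.3	72.7	48.4	93.2
7.1	371	193566	3522	39.2	70.9	50.5	97.0
7.1.1	97	37599	918	59.2	62.9	61.0	99.6
7.1.2	121	30174	1515	32.9	47.1	38.8	99.0
7.2	213	95510	2483	39.2	61.0	47.7	98.4
7.3	215	826072	2042	36.8	61.4	46.0	98.2
8	518	1145524	4659	40.1	66.6	50.1	96.1
8.1	78	117320	1017	25.0	34.6	29.0	99.2
8.2	452	928736	4445	42.4	66.8	51.8	96.8
8.2.2	241	220979	2605	46.1	61.4	52.7	98.5
9	213	84204	2006	45.8	79.8	58.2	98.6
9.1	195	48772	1870	47.1	74.9	57.8	98.8
10	226	651044	2237	32.2	59.3	41.7	97.9
10.1	152	465785	1696	23.2	38.2	28.9	98.4
10.2	70	70881	1035	51.5	50.0	50.7	99.6
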