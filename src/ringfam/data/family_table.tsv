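name	alias	gene_id	gene_length_bp	intron_count	uniprot_id	protein_length_aa	ring_subtype	tm_h_code	other_domains
VviATL3		VIT_09s0002g00220	1245	0	F6HXK6	304	PxC	1	
VviATL4	VviRHX1A	VIT_15s0021g00890	1827	3	D7SM36	203	PxC	0	
VviATL18		VIT_11s0118g00780	1113	2	F6HCI8	193	PC	0	
VviATL23a		VIT_18s0001g01060	935	0	F6H0E4	114	PxC	0.5	
VviATL23b		VIT_18s0001g01050	399	0	E0CQX3	132	PxC	1	
VviATL24		VIT_17s0000g06460	4466	4	D7SI89	217	PxC	1	
VviATL27		VIT_00s0264g00020	2554	4	D7T1R5	235	PxC	1	
VviATL43		VIT_11s0052g00530	1576	2	D7SQD9	457	PxC	3	
VviATL54a		VIT_18s0001g06640	3221	1	F6H0Y5	405	PxC	1	
VviATL54b		VIT_03s0017g00670	2774	1	F6HTI0	427	PxC	1	
VviATL55	VviRING1	VIT_07s0191g00230	1844	0	F6HRP9	372	PxC	1	
VviATL63		VIT_06s0004g06930	804	0	D7SJU6	267	PxC	1	
VviATL65		VIT_03s0063g01890	2068	0	F6HQI8	396	PxC	1	
VviATL82		VIT_01s0026g02540	820	0	F6HPQ9	233	PC	0.5	
VviATL83		VIT_17s0000g08400	1887	0	F6GSQ4	143	PC	0	
VviATL84		VIT_06s0004g00120	1853	0	F6GUP5	368	PC	0.5	zf-RING_3
VviATL85		VIT_12s0034g01400	786	0	F6H965	261	PC	0.5	
VviATL86		VIT_12s0034g01390	1434	1	D7T016	451	PC	0.5	
VviATL87		VIT_18s0001g03270	1002	0	F6H0T2	333	PC	0.5	zf-RING_3
VviATL88		VIT_08s0040g00590	1320	0	F6HQR2	314	PC	0	zf-RING_3
VviATL89		VIT_06s0009g02350	4862	0	F6HAD8	336	PC	0	zf-RING_3
VviATL90		VIT_06s0004g05090	1728	0	F6GUZ2	386	PC	0	zf-RING_3;DUF1117
VviATL91		VIT_13s0019g01980	11750	1	F6HNV7	763	PC	0	zf-RING_3;DUF1117;Asp
VviATL92		VIT_08s0007g00720	6094	2	F6HL86	516	PC	0.5	zf-RING_3;DUF1117
VviATL93		VIT_13s0156g00140	3799	0	F6HPS6	312	PC	0	zf-RING_3
VviATL94		VIT_17s0053g00320	1165	0	F6HVS8	369	PC	0	zf-RING_3
VviATL95		VIT_04s0008g02290	2454	4	D7SU02	293	PC	0.5	
VviATL96		VIT_08s0056g00320	7370	2	F6HMS0	590	PC	1	
VviATL97		VIT_11s0016g03190	925	0	D7TBH2	168	PC	0.5	
VviATL98		VIT_17s0000g04730	1691	0	F6GTF6	439	PC	0	
VviATL99		VIT_14s0083g00710	1285	0	F6GVT7	391	PC	0	
VviATL100		VIT_08s0040g02950	972	0	F6HQW4	285	PC	0.5	
VviATL101		VIT_18s0001g14530	2804	0	A5BX64	334	PC	0	zf-RING_3
VviATL102		VIT_02s0012g01440	1720	0	F6HT83	292	PxC	0	
VviATL103		VIT_19s0090g00400	1594	4	F6HEK0	220	PxC	1	
VviATL104		VIT_05s0051g00730	19438	5	F6HS63	190	PC	0	
VviATL105		VIT_13s0064g01030	4567	6	D7T2Z6	247	PC	0	
VviATL106		VIT_06s0004g01930	9252	6	D7SL69	252	PC	0	
VviATL107		VIT_18s0075g00220	25207	4	F6GY85	444	PC	1	PA
VviATL108		VIT_04s0023g03580	4487	8	F6GWM0	422	PC	1	PA;Rhodanese
VviATL109		VIT_11s0052g00360	396	0	D7SQF4	131	PxC	0	
VviATL110		VIT_11s0118g00760	8334	5	F6HCI6	542	PC	0	
VviATL111		VIT_02s0087g00420	10368	5	F6HJ39	561	PC	0	
VviATL112		VIT_19s0015g01000	3045	2	D7UAM0	343	PC	4	
VviATL113		VIT_11s0016g04450	4562	3	D7TBT7	407	PC	4	
VviATL114		VIT_04s0008g04280	8051	3	D7SUI3	401	PC	4	
VviATL115		VIT_09s0002g05120	6212	3	F6HX40	442	PC	4	
VviATL116		VIT_09s0002g05140	1686	3	F6HX42	309	PC	4	
VviATL117		VIT_09s0002g05130	950	2	F6HX41	208	PC	2	
VviATL118		VIT_12s0057g01330	971	2	F6HHR0	202	PC	0.5	
VviATL119		VIT_08s0040g00310	24289	3	F6HQS8	385	PC	4	
VviATL120		VIT_13s0019g01960	8052	7	D7TLR3	275	PC	2	
VviATL121		VIT_06s0004g05080	4108	7	F6GUZ3	284	PC	0.5	
VviATL122		VIT_17s0000g08210	7519	10	F6GSR5	433	PC	4	
VviATL123		VIT_03s0091g00480	3492	2	D7SXT7	278	PC	0	
VviATL124		VIT_04s0023g03460	576	0	A5B1V6	166	PxC	1	
VviATL125		VIT_00s0349g00040	562	0	F6H5I9	135	PC	0.5	
VviATL126		VIT_12s0028g01580	1624	2	F6H540	339	PC	0	
VviATL127		VIT_12s0028g01560	1080	2	F6H541	190	PC	0	
VviATL128		VIT_12s0028g01570	1440	2	E0CTW4	224	PC	0.5	
VviATL129		VIT_15s0048g02030	4833	4	F6I314	382	PC	5	
VviATL130		VIT_02s0025g04150	7750	4	F6HUF7	384	PC	5	
VviATL131		VIT_15s0048g01840	2566	2	D7U7K1	201	PxC	1	
VviATL132		VIT_13s0074g00370	8204	2	D7UBU6	209	PxC	0.5	
VviATL133		VIT_18s0089g00860	3502	2	D7SMW5	221	PxC	1	
VviATL134		VIT_06s0004g08080	1766	1	F6GUB5	263	PxC	1	
VviATL135		VIT_08s0058g01270	1007	0	F6GXX0	195	PxC	1	
VviATL136		VIT_15s0024g01990	414	0	F6I5A3	137	PxC	0	
VviATL137		VIT_13s0067g02880	1008	0	A5BMU1	197	PxC	1	
VviATL138		VIT_03s0038g03930	542	0	F6I0R1	129	PxC	1	
VviATL139		VIT_18s0122g00870	794	0	F6I6U9	184	PxC	1	
VviATL140		VIT_07s0031g02250	872	0	D7SWC6	182	PxC	1	
VviATL141		VIT_11s0065g01210	696	0	F6H9R6	167	PxC	1	
VviATL142		VIT_15s0046g02070	1042	0	F6I654	197	PxC	1	
VviATL143		VIT_13s0084g00140	753	1	D7TX41	191	PxC	1	
VviATL144		VIT_02s0025g01430	3689	1	D7TVF6	386	PxC	1	GUB_WAK_bind
VviATL145		VIT_16s0098g00250	2508	1	F6H7E1	367	PxC	1	
VviATL146		VIT_15s0046g00930	1884	1	D7UCP8	372	PxC	1	WAK_assoc
VviATL147		VIT_18s0001g06670	1321	0	F6H0Y6	398	PxC	2	
VviATL148		VIT_14s0128g00120	1618	0	A5BY68	420	PxC	2	
VviATL149		VIT_12s0028g02530	1016	0	F6H4X9	254	PxC	1	
VviATL150		VIT_10s0003g00850	1020	0	F6HM71	218	PxC	1	
VviATL151		VIT_11s0016g03420	9067	1	F6HH04	469	PxC	2	
VviATL152		VIT_11s0037g01400	1869	0	F6HYP7	543	PxC	1	
VviATL153		VIT_01s0026g00300	1412	2	F6HPM6	420	PxC	1	
VviATL154		VIT_14s0066g01610	1739	0	F6HV15	386	PxC	1	
VviATL155		VIT_07s0005g00710	1013	0	F6HZ62	263	PxC	1	
VviATL156		VIT_05s0077g01970	1374	0	F6H6W1	317	PxC	1	
VviATL157		VIT_13s0019g01020	480	0	F6HN68	159	PxC	1	
VviATL158		VIT_13s0019g01000	453	0	F6HN69	150	PxC	1	
VviATL159		VIT_13s0019g00990	503	0	F6HN70	167	PxC	1	
VviATL160		VIT_09s0002g01500	806	0	F6HXY3	140	PxC	1	
VviATL161		VIT_11s0016g01430	651	0	F6HGU1	178	PxC	1	
VviATL162		VIT_07s0005g03120	917	1	F6HZI2	264	PxC	1	
VviATL163		VIT_05s0049g00480	1694	1	F6H8L8	390	PxC	2	
VviATL164		VIT_15s0045g00330	1034	0	D7U5P0	338	PxC	1	
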