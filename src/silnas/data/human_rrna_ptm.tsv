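molecule	position	mod_code	percent	newly_identified	redundancy_count
5.8S	14	Um	5	no	1
5.8S	55	Ψ	60	no	1
5.8S	69	Ψ	61	no	1
5.8S	75	Gm	87	no	1
18S	27	Am	100	no	1
18S	34	Ψ	100	no	1
18S	36	Ψ	82	no	1
18S	93	Ψ	87	no	1
18S	99	Am	99	no	1
18S	105	Ψ	99	no	1
18S	109	Ψ	99	no	1
18S	116	Um	98	no	1
18S	119	Ψ	94	no	1
18S	121	Um	98	no	1
18S	159	Am	96	no	1
18S	166	Am	100	no	1
18S	172	Um	96	no	1
18S	174	Cm	92	no	1
18S	210	Ψ	83	no	1
18S	218	Ψ	100	no	1
18S	296	Ψ	25	no	1
18S	354	Um	20	no	1
18S	406	Ψ	87	no	1
18S	428	Um	76	no	1
18S	436	Gm	76	no	1
18S	462	Cm	100	no	1
18S	468	Am	99	no	1
18S	484	Am	97	no	1
18S	509	Gm	98	no	1
18S	512	Am	83	no	1
18S	517	Cm	100	no	1
18S	572	Ψ	97	no	1
18S	576	Am	96	no	1
18S	590	Am	72	no	1
18S	601	Gm	89	no	1
18S	609	Ψ	90	no	1
18S	621	Cm	62	yes	1
18S	627	Um	99	no	1
18S	644	Gm	98	no	1
18S	649	Ψ	93	no	1
18S	651	Ψ	93	no	1
18S	668	Am	99	no	1
18S	681	Ψ	67	no	1
18S	683	Gm	99	no	1
18S	686	Ψ	95	no	1
18S	797	Cm	68	no	1
18S	799	Um	98	no	1
18S	801	Ψ	100	no	1
18S	814	Ψ	100	no	1
18S	815	Ψ	100	no	1
18S	822	Ψ	99	no	1
18S	863	Ψ	95	no	1
18S	866	Ψ	88	no	1
18S	867	Gm	28	no	1
18S	897	Ψ	23	yes	1
18S	918	Ψ	42	no	1
18S	966	Ψ	89	no	1
18S	1004	Ψ	97	no	1
18S	1031	Am	97	no	1
18S	1045	Ψ	92	yes	1
18S	1046	Ψ	100	no	1
18S	1056	Ψ	93	no	1
18S	1081	Ψ	94	no	1
18S	1136	Ψ	7	yes	1
18S	1174	Ψ	100	no	1
18S	1177	Ψ	100	no	1
18S	1232	Ψ	98	yes	1
18S	1238	Ψ	97	no	1
18S	1244	Ψ	100	no	1
18S	1248	m1acp3Ψ	100	no	1
18S	1272	Cm	47	no	1
18S	1288	Um	98	no	1
18S	1326	Um	100	no	1
18S	1328	Gm	100	no	1
18S	1337	ac4C	79	no	1
18S	1347	Ψ	98	no	1
18S	1367	Ψ	98	no	1
18S	1383	Am	98	no	1
18S	1391	Cm	95	no	1
18S	1442	Um	78	no	1
18S	1445	Ψ	90	no	1
18S	1447	Gm	34	no	1
18S	1490	Gm	100	no	1
18S	1625	Ψ	79	no	1
18S	1639	m7G	100	no	1
18S	1643	Ψ	96	no	1
18S	1668	Um	8	no	1
18S	1678	Am	94	no	1
18S	1692	Ψ	98	no	1
18S	1703	Cm	92	no	1
18S	1804	Um	86	no	1
18S	1832	m6A	99	no	1
18S	1842	ac4C	99	no	1
18S	1850	m62A	94	no	1
18S	1851	m62A	94	no	1
28S	389	Am	98	no	1
28S	391	Am	98	no	1
28S	1303	Gm	71	no	1
28S	1309	m1A	100	no	1
28S	1310	Am	44	no	1
28S	1313	Am	100	no	1
28S	1327	Cm	92	no	1
28S	1509	Gm	99	no	1
28S	1511	Am	99	no	1
28S	1521	Am	109	no	1
28S	1523	Ψ	88	no	1
28S	1569	Ψ	68	no	1
28S	1612	Gm	100	no	1
28S	1664	Ψ	97	no	1
28S	1670	Ψ	96	no	1
28S	1731	Ψ	100	no	1
28S	1747	Gm	89	no	1
28S	1760	Um	70	yes	1
28S	1766	Ψ	40	no	1
28S	1768	Ψ	100	yes	1
28S	1769	Ψ	100	no	1
28S	1779	Ψ	100	no	1
28S	1847	Ψ	95	no	1
28S	1849	Ψ	95	no	1
28S	1858	Am	96	no	1
28S	1868	Cm	35	no	1
28S	2338	Cm	99	no	1
28S	2350	Am	100	no	1
28S	2351	Gm	100	no	1
28S	2352	Cm	90	no	1
28S	2388	Am	73	no	1
28S	2402	Um	87	no	1
28S	2409	Cm	98	no	1
28S	2411	Gm	90	no	1
28S	2495	Ψ	92	no	1
28S	2619	Ψ	90	yes	1
28S	2774	Am	84	no	1
28S	2791	Cm	93	no	1
28S	2802	Am	92	no	1
28S	2811	Cm	87	no	1
28S	2824	Um	99	no	1
28S	2826	Ψ	20	no	1
28S	2830	Ψ	9	no	1
28S	2848	Cm	72	no	1
28S	2863	Gm	49	no	1
28S	3606	Gm	96	yes	1
28S	3616	Ψ	89	no	1
28S	3618	Ψ	95	no	1
28S	3674	Ψ	99	no	1
28S	3680	Cm	100	no	1
28S	3694	Ψ	100	no	1
28S	3697	Am	88	no	1
28S	3703	Am	100	no	1
28S	3709	Ψ	72	no	1
28S	3713	Ψ	98	no	1
28S	3723	Gm	83	no	1
28S	3737	Ψ	85	no	1
28S	3739	Am	90	no	1
28S	3741	Ψ	100	no	1
28S	3743	Ψ	100	no	1
28S	3747	Ψ	100	no	1
28S	3749	Ψ	100	no	1
28S	3761	m5C	100	no	1
28S	3764	Am	96	no	1
28S	3771	Gm	100	no	1
28S	3787	Cm	80	no	1
28S	3797	Ψm	100	no	1
28S	3801	Ψ	50	no	1
28S	3804	Am	92	no	1
28S	3809	Am	100	no	1
28S	3820	Cm	100	no	1
28S	3823	Ψ	66	no	1
28S	3830	Ψ	92	no	1
28S	3832	Ψ	100	no	1
28S	3846	Am	43	no	1
28S	3848	Cm	67	no	1
28S	3863	Ψ	33	no	1
28S	3866	Cm	99	no	1
28S	3878	Gm	98	no	1
28S	3899	Ψ	100	no	1
28S	3904	Um	96	no	1
28S	3923	Gm	80	no	1
28S	3938	Ψ	93	no	1
28S	4020	Gm	83	no	1
28S	4032	Cm	100	no	1
28S	4166	Gm	98	no	1
28S	4190	m6A	100	no	1
28S	4197	Um	97	no	1
28S	4198	Gm	92	no	1
28S	4263	Ψ	98	no	1
28S	4266	Ψ	90	no	1
28S	4269	Ψ	93	no	1
28S	4276	Um	88	no	1
28S	4282	Ψ	83	no	1
28S	4323	Ψ	95	no	1
28S	4331	Ψ	93	no	1
28S	4340	Gm	99	no	1
28S	4362	Gm	97	no	1
28S	4373	Ψ	96	no	1
28S	4390	Ψ	99	no	1
28S	4393	Ψ	97	no	1
28S	4401	Ψ	89	no	1
28S	4412	Ψ	100	no	1
28S	4417	m5C	100	no	1
28S	4426	Cm	98	no	1
28S	4427	Ψ	98	no	1
28S	4441	Ψ	87	no	1
28S	4463	Ψ	17	yes	1
28S	4464	Gm	91	no	1
28S	4468	Um	100	no	1
28S	4469	Gm	100	no	1
28S	4470	Ψ	100	no	1
28S	4491	Ψ	91	no	1
28S	4493	Am	87	no	1
28S	4500	m3U	120	no	1
28S	4502	Ψ	100	no	1
28S	4506	Cm	100	no	1
28S	4522	Ψ	98	no	1
28S	4541	Am	43	no	1
28S	4546	Ψ	100	no	1
28S	4549	Ψ	100	no	1
28S	4560	Am	37	no	1
28S	4588	Gm	75	no	1
28S	4590	Um	82	no	1
28S	4593	Gm	100	no	1
28S	4598	Ψ	92	no	1
28S	4606	Ψ	42	no	1
28S	4607	Gm	100	no	1
28S	4643	Ψ	39	no	1
28S	4659	Ψ	87	no	1
28S	4937	Ψ	81	no	1
28S	4966	Ψ	86	no	1
28S	4975	Ψ	72	no	1
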