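exon	c_start	c_end
1	1	31
2	32	93
3	94	186
4	187	264
5	265	357
6	358	530
7	531	649
8	650	831
9	832	960
10	961	1149
11	1150	1331
12	1332	1482
13	1483	1602
14	1603	1704
15	1705	1812
16	1813	1992
17	1993	2168
18	2169	2292
19	2293	2380
20	2381	2622
21	2623	2803
22	2804	2949
23	2950	3162
24	3163	3276
25	3277	3432
26	3433	3603
27	3604	3786
28	3787	3922
29	3923	4071
30	4072	4233
31	4234	4344
32	4345	4518
33	4519	4674
34	4675	4845
35	4846	5025
36	5026	5154
37	5155	5325
38	5326	5448
39	5449	5586
40	5587	5739
41	5740	5922
42	5923	6117
43	6118	6290
44	6291	6438
45	6439	6614
46	6615	6762
47	6763	6912
48	6913	7098
49	7099	7200
50	7201	7309
51	7310	7542
52	7543	7660
53	7661	7872
54	7873	8027
55	8028	8217
56	8218	8390
57	8391	8547
58	8548	8668
59	8669	8937
60	8938	9085
61	9086	9223
62	9224	9362
63	9363	9565
64	9566	9650
65	9651	9807
66	9808	9974
67	9975	10086
68	10087	10223
69	10224	10329
70	10330	10454
71	10455	10493
72	10494	10555
73	10556	10621
74	10622	10795
75	10796	10920
76	10921	10978
77	10979	11014
78	11015	11046
79	11047	11058
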