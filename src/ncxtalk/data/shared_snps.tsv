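index	rsid	chrom
1	rs112588918	19
2	rs2199575	19
3	rs57537848	19
4	rs11666329	19
5	rs2972559	19
6	rs71338733	19
7	rs73050205	19
8	rs199956232	19
9	rs4803763	19
10	rs4803764	19
11	rs142042446	19
12	rs12972156	19
13	rs12972970	19
14	rs34342646	19
15	rs283811	19
16	rs283815	19
17	rs6857	19
18	rs71352238	19
19	rs184017	19
20	rs2075650	19
21	rs157581	19
22	rs34095326	19
23	rs34404554	19
24	rs11556505	19
25	rs157582	19
26	rs59007384	19
27	rs769449	19
28	rs429358	19
29	rs75627662	19
30	rs10414043	19
31	rs7256200	19
32	rs483082	19
33	rs438811	19
34	rs34954997	19
35	rs5117	19
36	rs12721046	19
37	rs12721051	19
38	rs56131196	19
39	rs4420638	19
40	rs814573	19
41	rs157592	19
42	rs111789331	19
43	rs66626994	19
44	rs576224725	6
45	rs3095250	6
46	rs3132496	6
47	rs3095248	6
48	rs3130712	6
49	rs3130406	6
50	rs3130535	6
51	rs3130688	6
52	rs3134766	6
53	rs3130536	6
54	rs3134764	6
55	rs3134763	6
56	rs2394900	6
57	rs34763471	6
58	rs2394901	6
59	rs3095244	6
60	rs3134757	6
61	rs112077259	6
62	rs2894188	6
63	rs3095242	6
64	rs3095241	6
65	rs3130413	6
66	rs2394906	6
67	rs3130416	6
68	rs3130418	6
69	rs3134750	6
70	rs3130431	6
71	rs9264187	6
72	rs7769393	6
73	rs4458721	6
74	rs35899943	6
75	rs1980496	6
76	rs9268433	6
77	rs3793127	6
78	rs3763309	6
79	rs3763312	6
80	rs9269041	6
81	rs35743245	6
82	rs36096565	6
83	rs35972518	6
84	rs35917796	6
85	rs35380574	6
86	rs35395738	6
87	rs35472547	6
88	rs34939562	6
89	rs34924558	6
90	rs34496598	6
91	rs35525122	6
92	rs34350244	6
93	rs34535888	6
94	rs34553045	6
95	rs2760980	6
96	rs2760983	6
97	rs113134061	6
98	rs2760984	6
99	rs2454139	6
100	rs34117221	6
101	rs34331363	6
102	rs35226637	6
103	rs35653258	6
104	rs2647059	6
105	rs2647062	6
106	rs558721	6
107	rs679242	6
108	rs2760990	6
109	rs2647066	6
110	rs17425622	6
111	rs601148	6
112	rs601945	6
113	rs3130411	6
114	rs9271494	6
115	rs6917729	6
116	rs6605556	6
117	rs9268455	6
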