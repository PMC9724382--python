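# nucleoff YR translational positioning template, version 1
# weight(offset) = cos(2*pi*(offset - 72.5)/10.1), dinucleotide start offsets, dyad step centered at 72.5
# score(window) = sum_j weight_j * [base j in {C,T} and base j+1 in {A,G}] / 146
offset	weight
0	0.4358844185
1	0.8786934001
2	0.9922698724
3	0.7340585288
4	0.2008070729
5	-0.4076836149
6	-0.8634217049
7	-0.9956493480
8	-0.7548229392
9	-0.2311763221
10	0.3790884038
11	0.8473147050
12	0.9980655971
13	0.7748571071
14	0.2613219232
15	-0.3501264492
16	-0.8303879828
17	-0.9995162823
18	-0.7941416508
19	-0.2912147122
20	0.3208257698
21	0.8126579138
22	1.0000000000
23	0.8126579138
24	0.3208257698
25	-0.2912147122
26	-0.7941416508
27	-0.9995162823
28	-0.8303879828
29	-0.3501264492
30	0.2613219232
31	0.7748571071
32	0.9980655971
33	0.8473147050
34	0.3790884038
35	-0.2311763221
36	-0.7548229392
37	-0.9956493480
38	-0.8634217049
39	-0.4076836149
40	0.2008070729
41	0.7340585288
42	0.9922698724
43	0.8786934001
44	0.4358844185
45	-0.1702435557
46	-0.7125839641
47	-0.9879304397
48	-0.8931150162
49	-0.4636635320
50	0.1395153389
51	0.6904200206
52	0.9826352482
53	0.9066726012
54	0.4909940810
55	-0.1086521501
56	-0.6675881402
57	-0.9763894206
58	-0.9193530390
59	-0.5178496249
60	0.0776838473
61	0.6441104115
62	0.9691989992
63	0.9311440621
64	0.5442041828
65	-0.0466403904
66	-0.6200095475
67	-0.9610709404
68	-0.9420342635
69	-0.5700322582
70	0.0155518119
71	0.5953088643
72	0.9520131075
73	0.9520131075
74	0.5953088643
75	0.0155518119
76	-0.5700322582
77	-0.9420342635
78	-0.9610709404
79	-0.6200095475
80	-0.0466403904
81	0.5442041828
82	0.9311440621
83	0.9691989992
84	0.6441104115
85	0.0776838473
86	-0.5178496249
87	-0.9193530390
88	-0.9763894206
89	-0.6675881402
90	-0.1086521501
91	0.4909940810
92	0.9066726012
93	0.9826352482
94	0.6904200206
95	0.1395153389
96	-0.4636635320
97	-0.8931150162
98	-0.9879304397
99	-0.7125839641
100	-0.1702435557
101	0.4358844185
102	0.8786934001
103	0.9922698724
104	0.7340585288
105	0.2008070729
106	-0.4076836149
107	-0.8634217049
108	-0.9956493480
109	-0.7548229392
110	-0.2311763221
111	0.3790884038
112	0.8473147050
113	0.9980655971
114	0.7748571071
115	0.2613219232
116	-0.3501264492
117	-0.8303879828
118	-0.9995162823
119	-0.7941416508
120	-0.2912147122
121	0.3208257698
122	0.8126579138
123	1.0000000000
124	0.8126579138
125	0.3208257698
126	-0.2912147122
127	-0.7941416508
128	-0.9995162823
129	-0.8303879828
130	-0.3501264492
131	0.2613219232
132	0.7748571071
133	0.9980655971
134	0.8473147050
135	0.3790884038
136	-0.2311763221
137	-0.7548229392
138	-0.9956493480
139	-0.8634217049
140	-0.4076836149
141	0.2008070729
142	0.7340585288
143	0.9922698724
144	0.8786934001
145	0.4358844185
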