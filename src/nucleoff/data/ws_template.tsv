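# nucleoff W/S rotational positioning template, version 1
# weight(offset) = cos(2*pi*(offset - 73)/10.0), dyad at window offset 73
# score(window) = sum_i weight_i * (+1 if base i in {A,T} else -1) / 147
offset	weight
0	-0.3090169944
1	0.3090169944
2	0.8090169944
3	1.0000000000
4	0.8090169944
5	0.3090169944
6	-0.3090169944
7	-0.8090169944
8	-1.0000000000
9	-0.8090169944
10	-0.3090169944
11	0.3090169944
12	0.8090169944
13	1.0000000000
14	0.8090169944
15	0.3090169944
16	-0.3090169944
17	-0.8090169944
18	-1.0000000000
19	-0.8090169944
20	-0.3090169944
21	0.3090169944
22	0.8090169944
23	1.0000000000
24	0.8090169944
25	0.3090169944
26	-0.3090169944
27	-0.8090169944
28	-1.0000000000
29	-0.8090169944
30	-0.3090169944
31	0.3090169944
32	0.8090169944
33	1.0000000000
34	0.8090169944
35	0.3090169944
36	-0.3090169944
37	-0.8090169944
38	-1.0000000000
39	-0.8090169944
40	-0.3090169944
41	0.3090169944
42	0.8090169944
43	1.0000000000
44	0.8090169944
45	0.3090169944
46	-0.3090169944
47	-0.8090169944
48	-1.0000000000
49	-0.8090169944
50	-0.3090169944
51	0.3090169944
52	0.8090169944
53	1.0000000000
54	0.8090169944
55	0.3090169944
56	-0.3090169944
57	-0.8090169944
58	-1.0000000000
59	-0.8090169944
60	-0.3090169944
61	0.3090169944
62	0.8090169944
63	1.0000000000
64	0.8090169944
65	0.3090169944
66	-0.3090169944
67	-0.8090169944
68	-1.0000000000
69	-0.8090169944
70	-0.3090169944
71	0.3090169944
72	0.8090169944
73	1.0000000000
74	0.8090169944
75	0.3090169944
76	-0.3090169944
77	-0.8090169944
78	-1.0000000000
79	-0.8090169944
80	-0.3090169944
81	0.3090169944
82	0.8090169944
83	1.0000000000
84	0.8090169944
85	0.3090169944
86	-0.3090169944
87	-0.8090169944
88	-1.0000000000
89	-0.8090169944
90	-0.3090169944
91	0.3090169944
92	0.8090169944
93	1.0000000000
94	0.8090169944
95	0.3090169944
96	-0.3090169944
97	-0.8090169944
98	-1.0000000000
99	-0.8090169944
100	-0.3090169944
101	0.3090169944
102	0.8090169944
103	1.0000000000
104	0.8090169944
105	0.3090169944
106	-0.3090169944
107	-0.8090169944
108	-1.0000000000
109	-0.8090169944
110	-0.3090169944
111	0.3090169944
112	0.8090169944
113	1.0000000000
114	0.8090169944
115	0.3090169944
116	-0.3090169944
117	-0.8090169944
118	-1.0000000000
119	-0.8090169944
120	-0.3090169944
121	0.3090169944
122	0.8090169944
123	1.0000000000
124	0.8090169944
125	0.3090169944
126	-0.3090169944
127	-0.8090169944
128	-1.0000000000
129	-0.8090169944
130	-0.3090169944
131	0.3090169944
132	0.8090169944
133	1.0000000000
134	0.8090169944
135	0.3090169944
136	-0.3090169944
137	-0.8090169944
138	-1.0000000000
139	-0.8090169944
140	-0.3090169944
141	0.3090169944
142	0.8090169944
143	1.0000000000
144	0.8090169944
145	0.3090169944
146	-0.3090169944
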