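# Kabat-annotated lambda light-chain (VL) reference profile, sheep-consensus-like.
# One residue per line: <Kabat code>\t<amino acid>.
# Curated data, configurable.
1	Q
2	S
3	V
4	L
5	T
6	Q
7	P
8	P
9	S
10	V
11	S
12	G
13	A
14	P
15	G
16	Q
17	R
18	V
19	T
20	I
21	S
22	S
23	C
24	S
25	G
26	S
27	S
28	S
29	N
30	I
31	G
32	N
33	N
34	Y
35	W
36	Y
37	Q
38	Q
39	L
40	P
41	G
42	T
43	A
44	P
45	K
46	L
47	L
48	I
49	Y
50	G
51	N
52	S
53	N
54	R
55	P
56	S
57	G
58	V
59	P
60	D
61	R
62	F
63	S
64	G
65	S
66	K
67	S
68	G
69	T
70	S
71	A
72	S
73	L
74	A
75	I
76	T
77	G
78	L
79	Q
80	A
81	E
82	D
83	E
84	A
85	D
86	Y
87	Y
88	C
89	Q
90	S
91	Y
92	D
93	S
94	S
95	L
96	S
97	G
98	V
99	F
100	G
101	G
102	G
103	T
104	K
105	L
106	T
107	V
108	L
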