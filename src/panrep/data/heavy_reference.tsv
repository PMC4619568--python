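# Kabat-annotated heavy-chain (VH) reference profile, sheep-consensus-like.
# One residue per line: <Kabat code>\t<amino acid>. Insertion letters are
# uppercase suffixes (82A sorts between 82 and 83). Curated data, configurable:
# substitute your own profile via the reference-path options.
1	E
2	V
3	Q
4	L
5	Q
6	E
7	S
8	G
9	G
10	G
11	L
12	V
13	Q
14	P
15	G
16	G
17	S
18	L
19	R
20	L
21	S
22	C
23	A
24	A
25	S
26	G
27	F
28	T
29	F
30	S
31	S
32	Y
33	A
34	M
35	S
36	W
37	V
38	R
39	Q
40	A
41	P
42	G
43	K
44	G
45	L
46	E
47	W
48	V
49	S
50	T
51	I
52	S
53	S
54	G
55	G
56	S
57	Y
58	T
59	Y
60	Y
61	A
62	D
63	S
64	V
65	K
66	R
67	F
68	T
69	I
70	S
71	R
72	D
73	N
74	S
75	K
76	N
77	T
78	L
79	Y
80	L
81	Q
82	M
82A	N
82B	S
82C	L
83	R
84	A
85	E
86	D
87	T
88	A
89	V
90	Y
91	Y
92	C
93	A
94	R
95	D
96	G
97	Y
98	S
99	S
100	G
101	W
102	Y
103	W
104	G
105	Q
106	G
107	T
108	L
109	V
110	T
111	V
112	S
113	S
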