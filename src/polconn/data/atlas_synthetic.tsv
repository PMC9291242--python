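roi	region	hemisphere
1	PreCG	L
2	PreCG	L
3	PreCG	L
4	PreCG	L
5	PreCG	R
6	PreCG	R
7	PreCG	R
8	SFGdor	L
9	SFGdor	L
10	SFGdor	L
11	SFGdor	L
12	SFGdor	R
13	SFGdor	R
14	SFGdor	R
15	ORBsup	L
16	ORBsup	L
17	ORBsup	L
18	ORBsup	L
19	ORBsup	R
20	ORBsup	R
21	ORBsup	R
22	MFG	L
23	MFG	L
24	MFG	L
25	MFG	L
26	MFG	R
27	MFG	R
28	MFG	R
29	ORBmid	L
30	ORBmid	L
31	ORBmid	L
32	ORBmid	R
33	ORBmid	R
34	ORBmid	R
35	ORBmid	R
36	IFGoperc	L
37	IFGoperc	L
38	IFGoperc	L
39	IFGoperc	R
40	IFGoperc	R
41	IFGoperc	R
42	IFGoperc	R
43	IFGtriang	L
44	IFGtriang	L
45	IFGtriang	L
46	IFGtriang	R
47	IFGtriang	R
48	IFGtriang	R
49	IFGtriang	R
50	ORBinf	L
51	ORBinf	L
52	ORBinf	L
53	ORBinf	R
54	ORBinf	R
55	ORBinf	R
56	ROL	L
57	ROL	L
58	ROL	L
59	ROL	L
60	ROL	R
61	ROL	R
62	ROL	R
63	SMA	L
64	SMA	L
65	SMA	L
66	SMA	L
67	SMA	R
68	SMA	R
69	SMA	R
70	OLF	L
71	OLF	L
72	OLF	L
73	OLF	L
74	OLF	R
75	OLF	R
76	OLF	R
77	SFGmed	L
78	SFGmed	L
79	SFGmed	L
80	SFGmed	L
81	SFGmed	R
82	SFGmed	R
83	SFGmed	R
84	ORBsupmed	L
85	ORBsupmed	L
86	ORBsupmed	L
87	ORBsupmed	R
88	ORBsupmed	R
89	ORBsupmed	R
90	ORBsupmed	R
91	REC	L
92	REC	L
93	REC	L
94	REC	R
95	REC	R
96	REC	R
97	REC	R
98	INS	L
99	INS	L
100	INS	L
101	INS	R
102	INS	R
103	INS	R
104	INS	R
105	ACG	L
106	ACG	L
107	ACG	L
108	ACG	R
109	ACG	R
110	ACG	R
111	DCG	L
112	DCG	L
113	DCG	L
114	DCG	L
115	DCG	R
116	DCG	R
117	DCG	R
118	PCG	L
119	PCG	L
120	PCG	L
121	PCG	L
122	PCG	R
123	PCG	R
124	PCG	R
125	HIP	L
126	HIP	L
127	HIP	L
128	HIP	L
129	HIP	R
130	HIP	R
131	HIP	R
132	PHG	L
133	PHG	L
134	PHG	L
135	PHG	R
136	PHG	R
137	PHG	R
138	PHG	R
139	AMYG	L
140	AMYG	L
141	AMYG	L
142	AMYG	R
143	AMYG	R
144	AMYG	R
145	AMYG	R
146	CAL	L
147	CAL	L
148	CAL	L
149	CAL	R
150	CAL	R
151	CAL	R
152	CAL	R
153	CUN	L
154	CUN	L
155	CUN	L
156	CUN	R
157	CUN	R
158	CUN	R
159	CUN	R
160	LING	L
161	LING	L
162	LING	L
163	LING	R
164	LING	R
165	LING	R
166	SOG	L
167	SOG	L
168	SOG	L
169	SOG	L
170	SOG	R
171	SOG	R
172	SOG	R
173	MOG	L
174	MOG	L
175	MOG	L
176	MOG	L
177	MOG	R
178	MOG	R
179	MOG	R
180	IOG	L
181	IOG	L
182	IOG	L
183	IOG	L
184	IOG	R
185	IOG	R
186	IOG	R
187	FFG	L
188	FFG	L
189	FFG	L
190	FFG	R
191	FFG	R
192	FFG	R
193	FFG	R
194	PoCG	L
195	PoCG	L
196	PoCG	L
197	PoCG	R
198	PoCG	R
199	PoCG	R
200	PoCG	R
201	SPG	L
202	SPG	L
203	SPG	L
204	SPG	R
205	SPG	R
206	SPG	R
207	SPG	R
208	IPL	L
209	IPL	L
210	IPL	L
211	IPL	R
212	IPL	R
213	IPL	R
214	IPL	R
215	SMG	L
216	SMG	L
217	SMG	L
218	SMG	R
219	SMG	R
220	SMG	R
221	ANG	L
222	ANG	L
223	ANG	L
224	ANG	L
225	ANG	R
226	ANG	R
227	ANG	R
228	PCUN	L
229	PCUN	L
230	PCUN	L
231	PCUN	L
232	PCUN	R
233	PCUN	R
234	PCUN	R
235	PCL	L
236	PCL	L
237	PCL	L
238	PCL	L
239	PCL	R
240	PCL	R
241	PCL	R
242	CAU	L
243	CAU	L
244	CAU	L
245	CAU	R
246	CAU	R
247	CAU	R
248	CAU	R
249	STG	L
250	STG	L
251	STG	L
253	STG	R
254	STG	R
255	STG	R
256	STG	R
257	MTG	L
258	MTG	L
259	MTG	L
260	MTG	R
261	MTG	R
262	MTG	R
263	MTG	R
264	ITG	L
265	ITG	L
266	ITG	L
267	ITG	R
268	ITG	R
269	ITG	R
252	excluded	-
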