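frequency_khz,level_db
10,43.001
11,42.297
12,41.655
13,41.065
14,40.518
15,40.010
16,39.534
17,39.087
18,38.666
19,38.269
20,37.891
21,37.533
22,37.192
23,36.866
24,36.554
25,36.255
26,35.969
27,35.694
28,35.429
29,35.174
30,34.929
31,34.692
32,34.463
33,34.242
34,34.028
35,33.821
36,33.621
37,33.427
38,33.239
39,33.056
40,32.880
41,32.708
42,32.542
43,32.380
44,32.224
45,32.072
46,31.924
47,31.780
48,31.641
49,31.506
50,31.375
51,31.248
52,31.124
53,31.005
54,30.889
55,30.776
56,30.667
57,30.561
58,30.459
59,30.360
60,30.264
61,30.171
62,30.081
63,29.994
64,29.911
65,29.830
66,29.752
67,29.677
68,29.605
69,29.536
70,29.469
71,29.405
72,29.344
73,29.285
74,29.229
75,29.176
76,29.124
77,29.076
78,29.030
79,28.986
80,28.944
81,28.905
82,28.868
83,28.833
84,28.800
85,28.769
86,28.741
87,28.715
88,28.690
89,28.668
90,28.647
91,28.628
92,28.612
93,28.597
94,28.583
95,28.572
96,28.562
97,28.554
98,28.547
99,28.542
100,28.539
101,28.537
102,28.537
103,28.537
104,28.540
105,28.543
106,28.548
107,28.555
108,28.562
109,28.571
110,28.581
111,28.591
112,28.604
113,28.617
114,28.631
115,28.646
116,28.662
117,28.679
118,28.697
119,28.716
120,28.735
121,28.756
122,28.777
123,28.799
124,28.822
125,28.845
126,28.869
127,28.894
128,28.920
129,28.946
130,28.972
131,29.000
132,29.027
133,29.055
134,29.084
135,29.113
136,29.143
137,29.173
138,29.204
139,29.235
140,29.266
141,29.298
142,29.330
143,29.362
144,29.395
145,29.428
146,29.461
147,29.495
148,29.528
149,29.562
150,29.597
151,29.631
152,29.666
153,29.701
154,29.736
155,29.771
156,29.807
157,29.843
158,29.878
159,29.914
160,29.950
161,29.986
162,30.023
163,30.059
164,30.095
165,30.132
166,30.169
167,30.205
168,30.242
169,30.279
170,30.316
171,30.353
172,30.390
173,30.427
174,30.464
175,30.501
176,30.538
177,30.575
178,30.612
179,30.649
180,30.686
181,30.723
182,30.760
183,30.797
184,30.834
185,30.871
186,30.908
187,30.945
188,30.982
189,31.019
190,31.056
191,31.093
192,31.130
193,31.166
194,31.203
195,31.240
196,31.276
197,31.313
198,31.349
199,31.386
200,31.422
201,31.458
202,31.495
203,31.531
204,31.567
205,31.603
206,31.639
207,31.675
208,31.711
209,31.746
210,31.782
211,31.818
212,31.853
213,31.889
214,31.924
215,31.959
216,31.995
217,32.030
218,32.065
219,32.100
220,32.135
221,32.169
222,32.204
223,32.239
224,32.273
225,32.308
226,32.342
227,32.376
228,32.410
229,32.444
230,32.478
231,32.512
232,32.546
233,32.580
234,32.613
235,32.647
236,32.680
237,32.714
238,32.747
239,32.780
240,32.813
241,32.846
242,32.879
243,32.912
244,32.945
245,32.977
246,33.010
247,33.042
248,33.075
249,33.107
250,33.139
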