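# synthetic Gompertz-Makeham lifetable fixture: q(a)=1-exp(-(4.0e-4+1.2e-5*exp(0.105*a))), life expectancy ~80.1y; columns: age qx
0	0.00041192
1	0.00041324
2	0.00041472
3	0.00041636
4	0.00041818
5	0.00042020
6	0.00042244
7	0.00042494
8	0.00042770
9	0.00043078
10	0.00043420
11	0.00043799
12	0.00044221
13	0.00044689
14	0.00045209
15	0.00045786
16	0.00046428
17	0.00047140
18	0.00047932
19	0.00048811
20	0.00049787
21	0.00050871
22	0.00052076
23	0.00053413
24	0.00054899
25	0.00056549
26	0.00058382
27	0.00060418
28	0.00062679
29	0.00065191
30	0.00067980
31	0.00071078
32	0.00074519
33	0.00078341
34	0.00082586
35	0.00087300
36	0.00092536
37	0.00098352
38	0.00104811
39	0.00111984
40	0.00119952
41	0.00128800
42	0.00138627
43	0.00149541
44	0.00161662
45	0.00175123
46	0.00190072
47	0.00206674
48	0.00225110
49	0.00245584
50	0.00268319
51	0.00293565
52	0.00321599
53	0.00352727
54	0.00387290
55	0.00425665
56	0.00468271
57	0.00515573
58	0.00568086
59	0.00626380
60	0.00691087
61	0.00762909
62	0.00842622
63	0.00931084
64	0.01029248
65	0.01138165
66	0.01259000
67	0.01393040
68	0.01541706
69	0.01706569
70	0.01889359
71	0.02091989
72	0.02316561
73	0.02565391
74	0.02841027
75	0.03146265
76	0.03484172
77	0.03858107
78	0.04271743
79	0.04729087
80	0.05234503
81	0.05792732
82	0.06408909
83	0.07088580
84	0.07837713
85	0.08662706
86	0.09570380
87	0.10567974
88	0.11663117
89	0.12863791
90	0.14178273
91	0.15615051
92	0.17182717
93	0.18889826
94	0.20744713
95	0.22755276
96	0.24928698
97	0.27271132
98	0.29787322
99	0.32480170
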