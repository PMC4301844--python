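age_years,qx
0,0.000543217
1,0.000547393
2,0.000551972
3,0.000556992
4,0.000562496
5,0.00056853
6,0.000575146
7,0.000582399
8,0.000590351
9,0.00059907
10,0.000608628
11,0.000619107
12,0.000630596
13,0.000643192
14,0.000657002
15,0.000672142
16,0.000688741
17,0.000706939
18,0.000726891
19,0.000748765
20,0.000772745
21,0.000799037
22,0.000827861
23,0.000859461
24,0.000894106
25,0.000932087
26,0.000973728
27,0.00101938
28,0.00106943
29,0.00112429
30,0.00118445
31,0.00125039
32,0.00132268
33,0.00140194
34,0.00148882
35,0.00158407
36,0.00168848
37,0.00180295
38,0.00192843
39,0.00206598
40,0.00221677
41,0.00238206
42,0.00256325
43,0.00276187
44,0.00297957
45,0.0032182
46,0.00347976
47,0.00376645
48,0.00408067
49,0.00442505
50,0.00480249
51,0.00521613
52,0.00566943
53,0.00616618
54,0.00671051
55,0.00730696
56,0.00796046
57,0.00867645
58,0.00946085
59,0.0103201
60,0.0112613
61,0.0122922
62,0.0134212
63,0.0146575
64,0.0160112
65,0.0174931
66,0.0191153
67,0.0208908
68,0.0228337
69,0.0249593
70,0.0272845
71,0.0298273
72,0.0326076
73,0.0356467
74,0.0389676
75,0.0425954
76,0.046557
77,0.0508816
78,0.0556004
79,0.060747
80,0.0663572
81,0.0724696
82,0.0791251
83,0.086367
84,0.0942414
85,0.102797
86,0.112083
87,0.122155
88,0.133065
89,0.144871
90,0.157631
91,0.171401
92,0.186239
93,0.202202
94,0.219344
95,0.237715
96,0.25736
97,0.278316
98,0.300613
99,0.324268
100,1
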