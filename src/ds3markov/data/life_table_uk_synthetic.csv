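age,qx
0,0.00020843486
1,0.00020941797
2,0.00021051539
3,0.00021174042
4,0.00021310789
5,0.00021463437
6,0.00021633834
7,0.00021824043
8,0.0002203637
9,0.00022273385
10,0.00022537959
11,0.00022833296
12,0.00023162974
13,0.00023530984
14,0.00023941785
15,0.0002440035
16,0.00024912235
17,0.00025483637
18,0.00026121476
19,0.00026833478
20,0.00027628264
21,0.00028515458
22,0.00029505805
23,0.00030611295
24,0.00031845316
25,0.00033222808
26,0.00034760449
27,0.00036476857
28,0.0003839281
29,0.00040531504
30,0.00042918826
31,0.00045583674
32,0.00048558302
33,0.0005187871
34,0.00055585077
35,0.00059722252
36,0.00064340287
37,0.00069495046
38,0.00075248876
39,0.00081671359
40,0.00088840149
41,0.00096841904
42,0.0010577333
43,0.0011574234
44,0.0012686936
45,0.0013928874
46,0.001531504
47,0.0016862159
48,0.001858889
49,0.0020516051
50,0.0022666858
51,0.0025067209
52,0.0027745987
53,0.0030735397
54,0.0034071353
55,0.0037793888
56,0.004194763
57,0.0046582315
58,0.0051753365
59,0.0057522522
60,0.0063958553
61,0.0071138032
62,0.00791462
63,0.0088077914
64,0.0098038692
65,0.010914587
66,0.012152985
67,0.01353355
68,0.015072366
69,0.016787277
70,0.018698068
71,0.020826656
72,0.023197299
73,0.025836817
74,0.028774829
75,0.032044003
76,0.035680314
77,0.039723315
78,0.044216409
79,0.049207125
80,0.054747377
81,0.060893715
82,0.067707544
83,0.075255291
84,0.083608522
85,0.092843957
86,0.10304337
87,0.11429337
88,0.1266849
89,0.14031264
90,0.15527395
91,0.1716676
92,0.18959195
93,0.20914277
94,0.23041032
95,0.253476
96,0.2784081
97,0.305257
98,0.33404958
99,0.36478293
100,0.39741762
101,0.4318706
102,0.46800816
103,0.50563943
104,0.54451096
105,0.58430337
106,0.62463077
107,0.66504409
108,0.70503925
109,0.74407098
110,1
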