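age,qx
0,0.004
1,0.00017424
2,0.00017671
3,0.00017943
4,0.00018243
5,0.00018573
6,0.00018937
7,0.00019338
8,0.0001978
9,0.00020267
10,0.00020803
11,0.00021395
12,0.00022046
13,0.00022764
14,0.00023554
15,0.00024426
16,0.00025386
17,0.00026444
18,0.0002761
19,0.00028894
20,0.00030309
21,0.00031869
22,0.00033587
23,0.0003548
24,0.00037566
25,0.00039865
26,0.00042398
27,0.00045188
28,0.00048263
29,0.00051652
30,0.00055385
31,0.00059499
32,0.00064031
33,0.00069026
34,0.00074529
35,0.00080592
36,0.00087273
37,0.00094635
38,0.00102747
39,0.00111685
40,0.00121533
41,0.00132385
42,0.00144342
43,0.00157516
44,0.00172033
45,0.00188029
46,0.00205653
47,0.00225073
48,0.00246472
49,0.00270049
50,0.00296029
51,0.00324655
52,0.00356196
53,0.0039095
54,0.00429245
55,0.0047144
56,0.00517933
57,0.00569162
58,0.00625609
59,0.00687806
60,0.00756339
61,0.00831852
62,0.00915056
63,0.01006736
64,0.01107755
65,0.01219063
66,0.0134171
67,0.01476849
68,0.01625753
69,0.01789825
70,0.0197061
71,0.02169809
72,0.02389299
73,0.02631146
74,0.02897627
75,0.03191253
76,0.03514787
77,0.03871277
78,0.04264078
79,0.04696891
80,0.0517379
81,0.05699266
82,0.06278268
83,0.06916247
84,0.0761921
85,0.08393778
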