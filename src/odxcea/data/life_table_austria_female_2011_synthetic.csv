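# Synthetic life table approximating the 2011 Austrian female all-cause
# mortality schedule.  Generated from a Gompertz-Makeham hazard
# mu(x) = a*exp(b*x) + c with a=2.1666034597e-05, b=0.095, c=5e-4,
# calibrated so remaining life expectancy at age 50 is 33.0 years.
# Not official national statistics.
age,qx
40,0.0015148445
41,0.0016159388
42,0.0017270961
43,0.0018493169
44,0.0019837009
45,0.0021314565
46,0.002293912
47,0.0024725272
48,0.002668906
49,0.002884811
50,0.003122179
51,0.0033831375
52,0.003670024
53,0.0039854059
54,0.0043321032
55,0.0047132126
56,0.0051321345
57,0.0055926022
58,0.0060987135
59,0.0066549659
60,0.0072662944
61,0.0079381129
62,0.0086763592
63,0.009487544
64,0.0103788043
65,0.0113579608
66,0.0124335805
67,0.0136150443
68,0.0149126198
69,0.0163375396
70,0.017902086
71,0.0196196805
72,0.021504981
73,0.0235739831
74,0.0258441293
75,0.0283344231
76,0.0310655479
77,0.0340599921
78,0.0373421767
79,0.0409385864
80,0.044877901
81,0.0491911259
82,0.0539117188
83,0.0590757082
84,0.0647218009
85,0.0708914719
86,0.0776290304
87,0.0849816552
88,0.0929993884
89,0.1017350779
90,0.111244255
91,0.121584933
92,0.132817308
93,0.1450033458
94,0.1582062297
95,0.1724896498
96,0.1879169053
97,0.2045497975
98,0.2224472845
99,0.2416638764
100,0.262247748
101,0.2842385559
102,0.3076649538
103,0.332541814
104,1.0
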