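age,annual_death_probability
40,0.0013043337277207614
41,0.0013947300811766692
42,0.0014941566195968642
43,0.0016035143780396758
44,0.0017237940789250992
45,0.0018560850135056776
46,0.002001584793200095
47,0.002161610053949709
48,0.002337608204275301
49,0.0025311703158138253
50,0.002744045263826934
51,0.002978155234514084
52,0.0032356127259458973
53,0.003518739180062239
54,0.0038300853944462157
55,0.004172453874466653
56,0.0045489232988342315
57,0.004962875284571419
58,0.005418023650752869
59,0.005918446393989534
60,0.006468620602315251
61,0.007073460547635369
62,0.007738359209883367
63,0.008469233498080216
64,0.009272573444064878
65,0.010155495653087493
66,0.011125801300886253
67,0.012192038968260741
68,0.013363572600223056
69,0.014650654865980203
70,0.01606450617636211
71,0.017617399584540464
72,0.019322751751191185
73,0.021195220093290328
74,0.023250806152509032
75,0.025506965109957497
76,0.027982721233245546
77,0.03069878886295081
78,0.033677698321025636
79,0.03694392584467861
80,0.04052402630583569
81,0.04444676705711723
82,0.04874326073775168
83,0.05344709426314311
84,0.05859445049503186
85,0.0642242182297495
86,0.07037808513425896
87,0.07710060708851647
88,0.08443924604523212
89,0.0924443669851733
90,0.10116918282482128
91,0.11066963423002969
92,0.12100418922470436
93,0.1322335452970246
94,0.14442021446305864
95,0.15762796954893132
96,0.17192112794250972
97,0.18736364744413994
98,0.20401800788176647
99,0.22194385219819412
100,0.24119636220935878
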