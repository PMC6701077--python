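group_id,name,patterns
1,CH3,[CH3;X4]
2,CH2,[CH2;X4]
3,CH,[CH1;X4]
4,C,[CH0;X4]|[CH0;X3]
5,CH2=CH,[CH2]=[CH]
6,CH=CH,[CH]=[CH]
7,CH2=C,[CH2]=[C]|[CH2]=[c]
8,CH=C,[CH]=[CH0]|[CH]=[cH0]
9,ACH,[cH]
10,AC,[cH0]
11,ACCH3,[c][CH3;X4]
12,ACCH2,[c][CH2;X4]
13,ACCH,[c][CH;X4]
14,OH,[OH]
15,CH3OH,[CH3][OH]
16,H2O,[OH2]
17,ACOH,[c][OH]
18,CH3CO,[CH3][CH0]=O
19,CH2CO,[CH2][CH0]=O
20,CH=O,[CH]=O
21,CH3COO,[CH3]C(=O)[OH0]
22,CH2COO,[CH2]C(=O)[OH0]
23,HCOO,[CH](=O)[OH0]
24,CH3O,[CH3][OH0]
25,CH2O,[CH2][OH0]
26,CHO,[CH][OH0]
27,THF,[CH2;R][OH0]
28,CH3NH2,[CH3][NH2]
29,CH2NH2,[CH2][NH2]
30,CHNH2,[CH][NH2]
31,CH3NH,[CH3][NH]
32,CH2NH,[CH2][NH]
33,CHNH,[CH][NH]
34,CH3N,[CH3][N]|[CH3][n]
35,CH2N,[CH2][N]
36,ACNH2,[c][NH2]
37,C5H5N,n1[cH][cH][cH][cH][cH]1
38,C5H4N,n1[c][cH][cH][cH][cH]1|n1[cH][c][cH][cH][cH]1|n1[cH][cH][c][cH][cH]1
39,C5H3N,n1[c][c][cH][cH][cH]1|n1[c][cH][c][cH][cH]1|n1[c][cH][cH][c][cH]1|n1[c][cH][cH][cH][c]1|n1[cH][c][c][cH][cH]1|n1[cH][c][cH][c][cH]1
40,CH3CN,[CH3]C#N
41,CH2CN,[CH2]C#N
42,COOH,C(=O)[OH]
43,HCOOH,[CH](=O)[OH]
44,CH2Cl,[CH2]Cl
45,CHCl,[CH]Cl
46,CCl,[CH0]Cl
47,CH2Cl2,[CH2](Cl)Cl
48,CHCl2,[CH](Cl)Cl
49,CCl2,C(Cl)Cl
50,CHCl3,[CH](Cl)(Cl)Cl
51,CCl3,C(Cl)(Cl)(Cl)
52,CCl4,C(Cl)(Cl)(Cl)(Cl)
53,ACCl,[c]Cl
54,CH3NO2,[CH3][N+](=O)[O-]
55,CH2NO2,[CH2][N+](=O)[O-]
56,CHNO2,[CH][N+](=O)[O-]
57,ACNO2,[c][N+](=O)[O-]
58,CS2,C(=S)=S
59,CH3SH,[CH3][SH]
60,CH2SH,[CH2][SH]
61,Furfural,O=[CH]c1[cH][cH][cH]o1
62,DOH,[OH][CH2][CH2][OH]
63,I,[IH0]
64,Br,[BrH0]
65,CH#C,[CH]#C
66,C#C,C#C
67,DMSO,[CH3]S(=O)[CH3]
68,ACRY,[CH2]=[CH1][C]#N
69,Cl(C=C),[$(Cl[C]=[C])]
70,C=C,[CH0]=[CH0]
71,ACF,[c]F
72,DMF,[CH](=O)N([CH3])[CH3]
73,HCON(CH2)2,[CH](=O)N([CH2])[CH2]|[CH](=O)N([CH2])[CH3]
74,CF3,C(F)(F)F
75,CF2,C(F)F
76,CF,[C]F
77,COO,[CH0](=O)[OH0]|[cH0](=O)[oH0]
78,SiH3,[SiH3]
79,SiH2,[SiH2]
80,SiH,[SiH]
81,Si,[Si]
82,SiH2O,[SiH2][OH0]
83,SiHO,[SiH][OH0]
84,SiO,[Si][OH0]
85,NMP,[CH3]N1[CH2][CH2][CH2]C(=O)1
86,CCl3F,C(Cl)(Cl)(Cl)F
87,CCl2F,C(Cl)(Cl)F
88,HCCl2F,[CH](Cl)(Cl)F
89,HCClF,[CH](Cl)F
90,CClF2,C(Cl)(F)F
91,HCClF2,[CH](Cl)(F)F
92,CClF3,C(Cl)(F)(F)F
93,CCl2F2,C(Cl)(Cl)(F)F
94,CONH2,C(=O)[NH2]
95,CONHCH3,C(=O)[NH][CH3]
96,CONHCH2,C(=O)[NH][CH2]
97,CON(CH3)2,C(=O)N([CH3])[CH3]
98,CONCH3CH2,C(=O)N([CH3])[CH2]
99,CON(CH2)2,C(=O)N([CH2])[CH2]
100,C2H5O2,[OH0;!$(OC=O);!R][CH2;!R][CH2;!R][OH]
101,C2H4O2,[OH0;!$(OC=O);!R][CH;!R][CH2;!R][OH]|[OH0;!$(OC=O);!R][CH2;!R][CH;!R][OH]
102,CH3S,[CH3]S
103,CH2S,[CH2]S
104,CHS,[CH]S
105,MORPH,[CH2]1[CH2][NH][CH2][CH2]O1
106,C4H4S,[cH]1[cH][s;X2][cH][cH]1
107,C4H3S,[c]1[cH][s;X2][cH][cH]1|[cH]1[c][s;X2][cH][cH]1
108,C4H2S,[c]1[c][s;X2][cH][cH]1|[c]1[cH][s;X2][cH][c]1|[cH]1[c][s;X2][c][cH]1|[cH]1[c][s;X2][cH][c]1
109,NCO,N=C=O
118,(CH2)2SU,[CH2]S(=O)(=O)[CH2]
119,CH2CHSU,[CH2]S(=O)(=O)[CH]
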