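group_id,zero_free_bonds,simple,n_atoms,one_free_bond,n_hetero,in_ring,n_triple,n_double
1,False,False,1,True,0,False,0,0
2,False,False,1,False,0,False,0,0
3,False,False,1,False,0,False,0,0
4,False,False,1,False,0,False,0,0
5,False,False,2,True,0,False,0,1
6,False,False,2,False,0,False,0,1
7,False,False,2,False,0,False,0,1
8,False,False,2,False,0,False,0,1
9,False,False,1,False,0,True,0,0
10,False,False,1,False,0,True,0,0
11,False,False,2,False,0,True,0,0
12,False,False,2,False,0,True,0,0
13,False,False,2,False,0,True,0,0
14,False,False,1,True,1,False,0,0
15,True,False,2,False,1,False,0,0
16,True,False,1,False,1,False,0,0
17,False,False,2,False,1,True,0,0
18,False,False,3,True,1,False,0,1
19,False,False,3,False,1,False,0,1
20,False,False,2,True,1,False,0,1
21,False,False,4,True,2,False,0,1
22,False,False,4,False,2,False,0,1
23,False,False,3,True,2,False,0,1
24,False,False,2,True,1,False,0,0
25,False,False,2,False,1,False,0,0
26,False,False,2,False,1,False,0,0
27,False,False,2,False,1,True,0,0
28,True,False,2,False,1,False,0,0
29,False,False,2,True,1,False,0,0
30,False,False,2,False,1,False,0,0
31,False,False,2,True,1,False,0,0
32,False,False,2,False,1,False,0,0
33,False,False,2,False,1,False,0,0
34,False,False,2,False,1,False,0,0
35,False,False,2,False,1,False,0,0
36,False,False,2,False,1,True,0,0
37,True,False,6,False,1,True,0,0
38,False,False,6,True,1,True,0,0
39,False,False,6,False,1,True,0,0
40,True,False,3,False,1,False,1,0
41,False,False,3,True,1,False,1,0
42,False,False,3,True,2,False,0,1
43,True,False,3,False,2,False,0,1
44,False,True,2,True,1,False,0,0
45,False,True,2,False,1,False,0,0
46,False,True,2,False,1,False,0,0
47,True,False,3,False,2,False,0,0
48,False,True,3,True,2,False,0,0
49,False,True,3,False,2,False,0,0
50,True,False,4,False,3,False,0,0
51,False,True,4,True,3,False,0,0
52,True,False,5,False,4,False,0,0
53,False,True,2,False,1,True,0,0
54,False,False,4,True,3,False,0,1
55,False,False,4,False,3,False,0,1
56,False,False,4,False,3,False,0,1
57,False,False,4,False,3,True,0,1
58,True,False,3,False,2,False,0,2
59,True,False,2,False,1,False,0,0
60,False,False,2,True,1,False,0,0
61,True,False,7,False,2,True,0,1
62,True,False,4,False,2,False,0,0
63,False,True,1,True,1,False,0,0
64,False,True,1,True,1,False,0,0
65,False,False,2,True,0,False,1,0
66,False,False,2,False,0,False,1,0
67,True,False,4,False,2,False,0,1
68,True,False,4,False,1,False,1,1
69,False,True,3,True,1,False,0,0
70,False,False,2,False,0,False,0,1
71,False,True,2,False,1,True,0,0
72,True,False,5,False,2,False,0,1
73,False,False,5,False,2,False,0,1
74,False,True,4,True,3,False,0,0
75,False,True,3,False,2,False,0,0
76,False,True,2,False,1,False,0,0
77,False,False,3,False,2,False,0,1
78,False,False,1,True,1,False,0,0
79,False,False,1,False,1,False,0,0
80,False,False,1,False,1,False,0,0
81,False,False,1,False,1,False,0,0
82,False,False,2,False,2,False,0,0
83,False,False,2,False,2,False,0,0
84,False,False,2,False,2,False,0,0
85,True,False,7,False,2,False,0,1
86,True,False,5,False,4,False,0,0
87,False,True,4,True,3,False,0,0
88,True,False,4,False,3,False,0,0
89,False,True,3,True,2,False,0,0
90,False,True,4,True,3,False,0,0
91,True,False,4,False,3,False,0,0
92,True,False,5,False,4,False,0,0
93,True,False,5,False,4,False,0,0
94,False,False,3,True,2,False,0,1
95,False,False,4,True,2,False,0,1
96,False,False,4,False,2,False,0,1
97,False,False,5,True,2,False,0,1
98,False,False,5,False,2,False,0,1
99,False,False,5,False,2,False,0,1
100,False,False,4,True,2,False,0,0
101,False,False,4,False,2,False,0,0
102,False,False,2,True,1,False,0,0
103,False,False,2,False,1,False,0,0
104,False,False,2,False,1,False,0,0
105,True,False,6,False,2,False,0,0
106,True,False,5,False,1,True,0,0
107,False,False,5,True,1,True,0,0
108,False,False,5,False,1,True,0,0
109,False,False,3,True,2,False,0,2
118,False,False,5,False,3,False,0,2
119,False,False,5,False,3,False,0,2
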