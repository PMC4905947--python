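generation,population,births,deaths,n_objects,n_still_life,n_oscillator,n_spaceship,n_dies_out,n_unresolved
0,367,0,0,30,0,0,0,19,11
1,391,200,176,26,1,0,0,14,11
2,331,135,195,24,2,1,0,8,13
3,322,145,154,30,0,0,0,16,14
4,311,154,165,31,0,0,0,21,10
5,308,164,167,24,0,1,0,10,13
6,274,123,157,25,1,1,0,18,5
7,262,117,129,28,4,0,0,11,13
8,228,106,140,33,1,0,0,22,10
9,198,94,124,29,3,0,0,15,11
10,199,82,81,28,2,0,0,15,11
11,201,88,86,25,3,0,0,13,9
12,163,66,104,28,3,2,0,14,9
13,169,69,63,24,2,1,0,10,11
14,162,65,72,25,2,1,0,12,10
15,167,62,57,20,3,0,0,6,11
16,167,61,61,27,2,1,0,14,10
17,151,64,80,24,2,1,0,14,7
18,139,57,69,17,2,0,0,7,8
19,135,57,61,16,3,0,0,8,5
20,113,40,62,22,2,1,0,13,6
21,117,52,48,18,1,1,0,8,8
22,108,42,51,19,2,0,0,7,10
23,102,40,46,16,3,1,0,6,6
24,96,34,40,17,4,1,0,7,5
25,100,35,31,13,4,0,0,4,5
26,115,43,28,11,4,0,0,2,5
27,100,33,48,16,4,1,0,6,5
28,115,42,27,12,4,0,0,1,7
29,111,37,41,17,4,0,0,8,5
30,134,54,31,10,3,0,0,1,6
31,107,39,66,23,3,0,0,15,5
32,106,44,45,17,3,1,0,6,7
33,94,30,42,21,3,1,0,11,6
34,90,34,38,16,3,2,0,6,5
35,84,30,36,14,3,0,0,6,5
36,92,35,27,15,4,0,0,7,4
37,92,36,36,14,3,0,0,7,4
38,77,29,44,12,3,0,0,5,4
39,75,26,28,10,4,0,0,2,4
40,82,22,15,12,4,0,0,4,4
41,70,22,34,9,4,0,0,1,4
42,83,28,15,6,4,0,0,0,2
43,77,27,33,12,4,1,0,3,4
44,78,28,27,10,3,2,0,2,3
45,82,33,29,13,3,3,0,4,3
46,74,29,37,15,3,2,0,6,4
47,70,23,27,14,3,2,0,5,4
48,62,20,28,15,4,2,0,5,4
49,70,29,21,9,4,2,0,0,3
50,66,17,21,12,4,2,0,3,3
51,66,23,23,14,4,2,0,5,3
52,62,20,24,11,4,2,0,3,2
53,62,16,16,11,4,2,0,3,2
54,61,19,20,11,4,2,0,3,2
55,66,19,14,10,4,2,0,2,2
56,62,18,22,15,4,3,0,5,3
57,67,20,15,10,4,2,0,2,2
58,55,17,29,12,4,2,0,4,2
59,62,21,14,10,5,2,0,1,2
60,52,17,27,10,5,2,0,2,1
61,66,22,8,10,5,2,0,2,1
62,56,26,36,10,6,2,0,1,1
63,70,20,6,9,6,2,0,0,1
64,62,20,28,9,6,2,0,0,1
65,73,15,4,7,5,1,0,0,1
66,75,22,20,11,5,3,0,2,1
67,95,29,9,8,4,1,0,2,1
68,51,14,58,13,4,1,0,4,4
69,55,18,14,10,4,1,0,1,4
70,54,17,18,8,5,1,0,0,2
71,52,7,9,9,5,1,0,0,3
72,56,10,6,9,5,1,0,0,3
73,56,8,8,8,6,1,0,0,1
74,58,7,5,9,6,1,1,1,0
75,56,10,12,9,6,1,0,0,2
76,65,15,6,9,6,1,0,0,2
77,61,14,18,13,5,1,0,6,1
78,66,17,12,10,5,1,0,2,2
79,62,17,21,13,5,2,0,4,2
80,61,15,16,10,5,1,0,2,2
81,58,12,15,11,5,1,0,2,3
82,62,15,11,8,5,1,0,1,1
83,58,17,21,11,5,1,0,3,2
84,51,10,17,10,5,1,0,3,1
85,48,9,12,11,6,1,0,3,1
86,44,5,9,9,5,1,0,2,1
87,45,7,6,9,5,2,0,1,1
88,46,9,8,9,5,2,0,1,1
89,45,7,8,8,5,1,0,0,2
90,51,13,7,7,5,1,0,0,1
91,50,12,13,8,5,1,0,0,2
92,59,15,6,7,5,1,0,0,1
93,53,11,17,13,5,1,0,5,2
94,56,13,10,8,5,1,0,1,1
95,54,10,12,8,5,1,0,0,2
96,61,15,8,7,5,1,0,0,1
97,60,11,12,9,5,1,0,2,1
98,69,18,9,9,5,1,0,1,2
99,64,16,21,12,5,1,0,4,2
100,72,23,15,7,4,1,0,1,1
101,61,16,27,11,5,2,0,2,2
102,62,16,15,9,4,1,0,3,1
103,70,18,10,9,4,1,0,2,2
104,58,17,29,12,4,1,0,4,3
105,62,19,15,9,4,1,0,0,4
106,62,16,16,11,4,1,0,2,4
107,66,17,13,10,4,1,0,1,4
108,68,18,16,9,4,1,0,0,4
109,78,23,13,9,4,1,0,0,4
110,79,23,22,10,4,1,0,2,3
111,73,21,27,13,4,1,0,3,5
112,89,28,12,8,5,1,0,0,2
113,84,29,34,12,4,3,0,3,2
114,97,35,22,9,3,1,0,1,4
115,92,32,37,14,3,1,0,5,5
116,105,42,29,11,3,1,0,3,4
117,104,40,41,14,3,2,0,5,4
118,112,44,36,15,3,2,0,5,5
119,104,43,51,21,3,2,0,10,6
120,109,43,38,14,3,1,0,5,5
121,104,43,48,13,2,2,0,1,8
122,121,48,31,13,2,2,0,2,7
123,113,45,53,15,3,3,1,3,5
124,128,46,31,9,3,2,1,0,3
125,126,42,44,13,3,3,1,1,5
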