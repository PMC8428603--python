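# POS SEQ GRADE
1 L 4
2 M 1
3 S 6
4 Y 6
5 A 3
6 D 4
7 T 4
8 W 5
9 F 1
10 H 4
11 V 6
12 K 4
13 G 4
14 T 1
15 G 6
16 K 8
17 P 8
18 M 9
19 C 8
20 A 9
21 V 9
22 S 8
23 T 8
24 M 9
25 T 9
26 H 8
27 L 9
28 S 9
29 D 9
30 H 8
31 D 9
32 L 9
33 Y 9
34 D 8
35 I 8
36 K 8
37 W 8
38 F 8
39 M 8
40 G 8
41 A 9
42 S 8
43 C 4
44 G 4
45 L 2
46 L 3
47 D 6
48 Y 6
49 R 2
50 Y 6
51 C 2
52 R 5
53 G 3
54 M 5
55 W 4
56 G 6
57 R 3
58 E 6
59 H 6
60 Y 1
61 K 1
62 M 1
63 G 4
64 D 3
65 K 1
66 P 1
67 L 6
68 S 4
69 I 1
70 P 2
71 S 4
72 W 2
73 K 5
74 A 2
75 R 4
76 M 1
77 V 5
78 L 5
79 I 4
80 C 4
81 L 1
82 P 4
83 S 3
84 V 1
85 F 1
86 N 3
87 T 5
88 G 5
89 H 2
90 T 1
91 N 2
92 M 3
93 Q 1
94 M 1
95 Y 3
96 S 1
97 C 2
98 D 2
99 M 3
100 T 3
101 C 1
102 Q 3
103 S 6
104 S 6
105 V 8
106 E 8
107 N 9
108 T 8
109 I 9
110 E 9
111 L 9
112 C 8
113 F 8
114 V 8
115 Q 9
116 V 9
117 T 9
118 V 9
119 H 9
120 L 8
121 P 9
122 G 8
123 W 8
124 A 8
125 T 8
126 P 8
127 G 8
128 R 9
129 K 8
130 T 8
131 Y 9
132 G 1
133 L 6
134 F 6
135 Q 1
136 P 4
137 T 6
138 T 1
139 Y 1
140 Y 1
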