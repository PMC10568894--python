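x,y,fitted_ref,se_ref
1,136.690804,135.5685328930,4.7155709371
2,134.904896,133.9876488944,3.4149568051
3,130.369528,133.1880654886,2.6617223398
4,135.515389,133.1442342052,2.4213631708
5,128.964514,133.8355684727,2.4778956452
6,135.563742,135.2458197458,2.5945174764
7,138.199794,137.4006479231,2.6628755825
8,137.093927,140.4285694940,2.7467357994
9,150.945033,144.5018878695,2.7467357994
10,145.164656,149.0772861735,2.7467357994
11,149.329422,153.7514863675,2.7467357994
12,158.986827,157.6759824447,2.7467357994
13,160.183248,160.1096247341,2.7467357994
14,169.366925,160.6113732359,2.7467357994
15,155.448064,159.0936086382,2.7467357994
16,162.633905,155.7883652859,2.7467357994
17,147.515721,150.8979082814,2.7467357994
18,140.403341,145.4638367439,2.7467357994
19,141.808581,140.7396546507,2.7467357994
20,135.184882,137.2961594681,2.7467357994
21,135.706815,135.1347479426,2.7467357994
22,129.351286,133.5117777493,2.7467357994
23,134.581395,131.9626476291,2.7467357994
24,134.402345,129.7775878751,2.7467357994
25,124.618869,126.5685785585,2.7467357994
26,126.605954,122.3411299360,2.7467357994
27,111.378833,117.4943327020,2.7467357994
28,116.933246,112.0361239851,2.7467357994
29,102.615087,105.8522799028,2.7467357994
30,100.245430,99.2715140082,2.7467357994
31,92.700751,92.9519396817,2.7467357994
32,99.236612,88.3986989153,2.7467357994
33,77.806518,86.5683831173,2.7467357994
34,74.094192,86.9040312469,2.7467357994
35,87.491660,88.1451920437,2.7467357994
36,86.971530,89.4673525565,2.7467357994
37,112.262130,90.4559098994,2.7467357994
38,92.602988,90.9718351528,2.7467357994
39,89.398085,90.3801077747,2.7467357994
40,74.179170,88.1942112633,2.7467357994
41,92.250929,85.6119425638,2.7467357994
42,79.633635,84.5688235480,2.7467357994
43,91.035200,86.0235457887,2.7467357994
44,87.213084,89.5259427517,2.7467357994
45,89.773334,93.5110730370,2.7467357994
46,100.433084,97.7529402121,2.7467357994
47,105.507285,102.8028085549,2.7467357994
48,109.999061,108.8075273373,2.7467357994
49,109.433381,114.9837037333,2.7467357994
50,115.023369,120.4660264162,2.7467357994
51,131.970789,124.7257269604,2.7467357994
52,133.818775,127.9596377489,2.7467357994
53,129.167490,130.1667097618,2.7467357994
54,131.974135,131.0466986738,2.7467357994
55,126.919647,130.7716416336,2.7467357994
56,129.120966,130.0743292831,2.7467357994
57,135.267906,130.1398502421,2.7467357994
58,126.495395,131.8580647678,2.7467357994
59,133.003068,134.9162458518,2.7467357994
60,139.538902,139.0416478545,2.7467357994
61,143.859474,144.0158375649,2.7467357994
62,147.519147,149.7023836420,2.7467357994
63,161.025486,155.8642504965,2.7467357994
64,153.979108,161.4397220908,2.7467357994
65,169.419344,164.6690498782,2.7467357994
66,162.823707,164.8422738464,2.7467357994
67,171.137938,161.9975541025,2.7467357994
68,163.198959,156.7454398727,2.7467357994
69,150.170625,150.2593182179,2.7467357994
70,132.095322,143.7202746741,2.7467357994
71,135.023819,138.4315784963,2.7467357994
72,134.097139,135.0921505164,2.7467357994
73,130.276398,133.5896053467,2.7467357994
74,140.214460,133.2061343286,2.7467357994
75,129.733767,133.0158582962,2.7467357994
76,145.133771,132.1311016640,2.7467357994
77,118.799589,129.9290927197,2.7467357994
78,127.669395,126.2258366806,2.7467357994
79,117.500101,120.9579302935,2.7467357994
80,122.152793,114.4836206092,2.7467357994
81,113.155143,107.7755057240,2.7467357994
82,97.127761,101.4982421280,2.7467357994
83,93.363492,96.4502781965,2.7467357994
84,88.649634,92.5141969498,2.7467357994
85,84.758608,89.7989982087,2.7467357994
86,94.311259,88.6870546531,2.7467357994
87,88.145514,89.1117873351,2.7467357994
88,99.029591,90.1149467400,2.7467357994
89,85.512363,90.5296931792,2.7467357994
90,81.835584,90.0337770843,2.6628755825
91,99.805939,89.7073190529,2.5945174764
92,89.079490,89.5358527286,2.4778956452
93,88.753235,89.4626426229,2.4213631708
94,81.236286,89.4619091848,2.6617223398
95,93.715033,89.5393178332,3.4149568051
96,90.766109,89.7271959441,4.7155709371
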