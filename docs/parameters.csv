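index,module,name,value
0,metabolic,c0,0.08
1,metabolic,c1,0.08
2,metabolic,c2,84211.0
3,metabolic,c3,2105.0
4,metabolic,c4,70182.0
5,metabolic,c5,350.87
6,metabolic,c6,50.0
7,metabolic,c7,180.0
8,metabolic,c8,0.22683
9,metabolic,c9,1350.0
10,metabolic,c10,3.5272
11,metabolic,c11,0.0684
12,metabolic,c12,1000.0
13,metabolic,c13,72.0
14,metabolic,c14,5.0
15,metabolic,T1,0.5
16,metabolic,T2,0.5
17,metabolic,T3,0.45
18,metabolic,T4,10.0
19,metabolic,T5,10.0
20,metabolic,T6,1000.0
21,metabolic,T7,10.0
22,metabolic,T8,10.0
23,metabolic,T9,150.0
24,metabolic,T10,0.5
25,metabolic,V,22.8
26,metabolic,K,1000.0
27,metabolic,DMI,11700.0
28,reproductive,c17,0.4
29,reproductive,c18,1.0
30,reproductive,c19,1.7
31,reproductive,c20,3.49
32,reproductive,c21,1.0
33,reproductive,c22,3.0
34,reproductive,c23,1.05
35,reproductive,c24,1.5
36,reproductive,c25,0.0007
37,reproductive,T11,0.3
38,reproductive,T12,15.0
39,reproductive,T14,0.5
40,reproductive,T15,15.0
41,reproductive,T16,16.0
42,reproductive,c_lh_cle,2.0
43,reproductive,c_p4_base,0.1
44,reproductive,ex_cl_cl,30.0
45,reproductive,ex_enz_pgf,1.0
46,reproductive,ex_oxy_pgf,10.0
47,reproductive,ex_p4_enz,1.0
48,reproductive,ex_pgf_iof,10.0
49,reproductive,ex_cl_iof,1.0
50,reproductive,T_foll_fsh,1.497
51,reproductive,T_fsh_foll,0.322
52,reproductive,T_cl_cl,0.2807
53,reproductive,c_cl_cl,0.0335
54,reproductive,c_cl_lh,0.4
55,reproductive,c_gnrh_syn,1.5
56,reproductive,T_gnrh_p4,0.5
57,reproductive,b_gnrh_rel,0.02
58,reproductive,c_gnrh_rel,10.0
59,reproductive,T_gnrh_e2,0.9
60,reproductive,ex_gnrh_e2,30.0
61,reproductive,T_gnrhrel_p4,0.15
62,reproductive,c_gnrh_auto,15.0
63,reproductive,T_gnrh_auto,0.2
64,reproductive,c_gnrh_cle,6.0
65,reproductive,c_lh_syn,10.0
66,reproductive,lh_pit_max,12.0
67,reproductive,T_lhsyn_p4,0.5
68,reproductive,b_lhsyn_e2,0.3
69,reproductive,T_lhsyn_e2,0.5
70,reproductive,b_lh_rel,0.004
71,reproductive,s_lh_gnrh,0.5
72,reproductive,s_lh_rel,0.75
73,reproductive,c_fsh_syn,0.22
74,reproductive,fsh_pit_max,3.2
75,reproductive,T_fsh_inh,0.8
76,reproductive,b_fsh_rel,0.0037
77,reproductive,s_fsh_gnrh,0.02
78,reproductive,s_fsh_rel,171.0
79,reproductive,c_fsh_cle,1.5
80,reproductive,c_foll_fsh,8.0
81,reproductive,b_foll_growth,0.15
82,reproductive,T_foll_self,0.5
83,reproductive,ex_foll_self,6.0
84,reproductive,c_foll_p4,1.0
85,reproductive,T_p4_foll,0.9
86,reproductive,ex_p4_foll,4.0
87,reproductive,T_ov_lh,0.85
88,reproductive,T_cl_lh,0.85
89,reproductive,s_cl_foll,0.5
90,reproductive,c_cl_decay,0.06
91,reproductive,c_cl_iof,4.0
92,reproductive,T_cl_iof,0.3
93,reproductive,c_p4_cl,3.2
94,reproductive,c_p4_cle,1.3
95,reproductive,b_e2,0.1
96,reproductive,T_pulse_ins,9.0
97,reproductive,ex_pulse_ins,20.0
98,reproductive,T_pulse_store,1.5
99,reproductive,b_foll_pulse,0.5
100,reproductive,c_e2_foll,2.0
101,reproductive,ex_e2_foll,1.0
102,reproductive,c_e2_cle,2.0
103,reproductive,b_inh,0.05
104,reproductive,c_inh_foll,0.75
105,reproductive,c_inh_cle,1.5
106,reproductive,c_enz_p4,0.029
107,reproductive,T_enz_p4,0.6
108,reproductive,c_enz_cle,0.01
109,reproductive,c_enz_reset,6.0
110,reproductive,T_enz_reset,0.3
111,reproductive,b_oxy,0.02
112,reproductive,c_oxy_e2,1.05
113,reproductive,T_oxy_e2,0.55
114,reproductive,c_oxy_cle,1.0
115,reproductive,c_pgf,9.0
116,reproductive,T_pgf_enz,0.9
117,reproductive,T_pgf_oxy,0.4
118,reproductive,c_pgf_sat,1.5
119,reproductive,T_pgf_sat,2.0
120,reproductive,c_pgf_cle,2.0
121,reproductive,c_iof,3.0
122,reproductive,T_iof_pgf,1.2
123,reproductive,T_iof_cl,0.2
124,reproductive,c_iof_cle,2.0
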