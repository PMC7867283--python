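compound_id,enzyme_id,prob_comb,p_activity
21,ache,0.67,0.58
21,nachr,0.65,0.58
44,ache,0.66,0.58
44,nachr,0.67,0.58
46,ache,0.67,0.57
46,nachr,0.66,0.57
47,ache,0.67,0.57
47,nachr,0.68,0.57
51,ache,0.7,0.57
51,nachr,0.71,0.57
67,ache,0.67,0.56
67,nachr,0.69,0.56
77,ache,0.69,0.62
77,nachr,0.71,0.62
95,ache,0.69,0.58
95,nachr,0.66,0.58
111,ache,0.66,0.56
111,nachr,0.67,0.56
131,ache,0.57,0.52
131,nachr,0.6,0.52
151,ache,0.71,0.61
151,nachr,0.71,0.61
163,ache,0.72,0.58
163,nachr,0.67,0.58
164,ache,0.72,0.58
164,nachr,0.68,0.58
199,ache,0.63,0.52
199,nachr,0.68,0.52
200,ache,0.67,0.52
200,nachr,0.67,0.52
231,ache,0.64,0.46
231,nachr,0.61,0.46
245,ache,0.54,0.39
245,nachr,0.6,0.39
273,ache,0.67,0.49
273,nachr,0.65,0.49
342,ache,0.73,0.61
342,nachr,0.67,0.61
434,ache,0.66,0.51
434,nachr,0.61,0.51
437,ache,0.73,0.61
437,nachr,0.67,0.61
438,ache,0.72,0.61
438,nachr,0.67,0.61
442,ache,0.71,0.6
442,nachr,0.74,0.6
450,ache,0.68,0.6
450,nachr,0.74,0.6
483,ache,0.62,0.54
483,nachr,0.65,0.54
709,ache,0.67,0.52
709,nachr,0.66,0.52
759,ache,0.62,0.53
759,nachr,0.66,0.53
787,ache,0.66,0.6
787,nachr,0.67,0.6
1015,ache,0.57,0.48
1015,nachr,0.64,0.48
1027,ache,0.63,0.53
1027,nachr,0.61,0.53
1086,ache,0.68,0.47
1086,nachr,0.66,0.47
1184,ache,0.65,0.49
1184,nachr,0.67,0.49
1195,ache,0.75,0.61
1195,nachr,0.7,0.61
1302,ache,0.65,0.49
1302,nachr,0.55,0.49
1350,ache,0.63,0.53
1350,nachr,0.67,0.53
1823,ache,0.56,0.47
1823,nachr,0.63,0.47
1892,ache,0.62,0.51
1892,nachr,0.6,0.51
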