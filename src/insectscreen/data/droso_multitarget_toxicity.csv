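compound_id,mutagenic,tumorigenic,reproductive_effective,irritant
21,No,No,No,No
44,No,No,No,No
46,No,No,No,No
47,No,No,No,No
51,No,No,No,No
67,No,No,No,No
77,No,No,No,No
95,No,No,No,No
111,No,No,No,No
131,No,No,No,No
151,No,No,No,No
163,No,No,No,High
164,No,No,No,High
199,No,No,No,No
200,No,No,No,No
231,No,No,No,No
245,No,No,No,High
273,High,High,High,High
342,No,No,No,No
434,No,No,No,No
437,No,No,No,High
438,No,No,No,High
442,No,No,No,No
450,No,No,No,High
483,No,No,No,No
709,No,No,No,Low
759,No,No,No,No
787,No,No,No,No
1015,No,No,No,No
1027,No,No,No,No
1086,No,No,No,No
1184,No,No,No,No
1195,No,No,No,No
1302,No,No,No,No
1350,No,No,No,No
1823,Low,No,No,No
1892,Low,No,No,No
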