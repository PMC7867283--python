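compound_id,enzyme_id,score,secondary_score,is_reference
21,ache,-122.7,35.26,0
21,nachr,-66.47,31.61,0
21,cht,-88.32,33.9,0
44,ache,-117.86,33.55,0
44,nachr,-80.01,27.08,0
44,cht,-106.16,32.12,0
46,ache,-127.86,32.36,0
46,nachr,-77.01,25.65,0
46,cht,-90.17,31.48,0
47,ache,-125.16,32.63,0
47,nachr,-83.84,28.45,0
47,cht,-107.76,42.33,0
51,ache,-138.59,36.68,0
51,nachr,-87.14,33.86,0
51,cht,-92.41,42.5,0
67,ache,-124.82,38.28,0
67,nachr,-91.09,24.51,0
67,cht,-99.81,33.76,0
77,ache,-133.84,22.53,0
77,nachr,-84.06,26.14,0
77,cht,-109.86,38.41,0
95,ache,-138.23,30.27,0
95,nachr,-79.21,23.47,0
95,cht,-116.49,33.67,0
111,ache,-125.26,35.09,0
111,nachr,-82.99,28.31,0
111,cht,-100.81,31.66,0
131,ache,-91.223,33.19,0
131,nachr,-71.29,24.81,0
131,cht,-99.12,29.23,0
151,ache,-142.6,23.97,0
151,nachr,-87.13,25.21,0
151,cht,-93.69,31.02,0
163,ache,-157.95,23.82,0
163,nachr,-78.03,26.01,0
163,cht,-114.73,32.97,0
164,ache,-157.91,25.68,0
164,nachr,-78.19,29.3,0
164,cht,-114.72,29.76,0
199,ache,-139.51,15.86,0
199,nachr,-97.99,25.26,0
199,cht,-123.03,35.87,0
200,ache,-139.3,37.46,0
200,nachr,-88.29,31.27,0
200,cht,-100.49,29.79,0
231,ache,-145.84,35.87,0
231,nachr,-85.64,24.74,0
231,cht,-101.52,41.8,0
245,ache,-137.39,14.49,0
245,nachr,-99.41,24.76,0
245,cht,-136.65,29.38,0
273,ache,-143.21,43.55,0
273,nachr,-90.84,27.57,0
273,cht,-127.36,31.78,0
342,ache,-141.28,34.26,0
342,nachr,-72.29,27.46,0
342,cht,-107.3,36.14,0
434,ache,-138.24,38.55,0
434,nachr,-69.37,29.14,0
434,cht,-103.72,31.53,0
437,ache,-143.25,34.95,0
437,nachr,-73.66,26.1,0
437,cht,-121.15,32.63,0
438,ache,-143.33,31.35,0
438,nachr,-74.69,25.49,0
438,cht,-121.91,36.05,0
442,ache,-147.15,21.3,0
442,nachr,-95.97,29.32,0
442,cht,-138.47,43.77,0
450,ache,-123.18,30.09,0
450,nachr,-97.99,25.94,0
450,cht,-112.14,45.4,0
483,ache,-112.04,30.03,0
483,nachr,-85.51,22.82,0
483,cht,-86.76,44.95,0
709,ache,-143.94,34.0,0
709,nachr,-88.47,26.91,0
759,ache,-119.82,28.98,0
759,nachr,-80.56,31.15,0
759,cht,-104.55,31.87,0
787,ache,-120.17,27.42,0
787,nachr,-77.32,24.15,0
787,cht,-103.2,43.73,0
1015,ache,-122.68,16.47,0
1015,nachr,-93.87,22.09,0
1015,cht,-132.03,29.89,0
1027,ache,-124.98,27.07,0
1027,nachr,-69.3,24.94,0
1027,cht,-80.09,40.3,0
1086,ache,-170.37,26.71,0
1086,nachr,-103.44,22.69,0
1086,cht,-141.82,43.52,0
1184,ache,-153.42,24.34,0
1184,nachr,-97.36,27.89,0
1184,cht,-125.27,40.64,0
1195,ache,-157.71,29.74,0
1195,nachr,-84.13,25.35,0
1195,cht,-124.31,43.36,0
1302,ache,-143.96,33.25,0
1302,nachr,-62.9,22.08,0
1302,cht,-93.11,29.37,0
1350,ache,-121.54,33.07,0
1350,nachr,-87.82,28.87,0
1350,cht,-98.21,30.85,0
1823,ache,-135.14,3.18,0
1823,nachr,-93.79,21.94,0
1823,cht,-110.04,31.33,0
1892,ache,-132.1,20.84,0
1892,nachr,-80.46,17.26,0
1892,cht,-108.72,29.68,0
methomyl,ache,-59.87,32.12,1
acetamiprid,nachr,-55.07,22.58,1
allosamidin,cht,-163.72,37.19,1
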