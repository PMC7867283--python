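compound_id,enzyme_id,score,secondary_score,is_reference
1800,ache,-174.03,51.28,0
1800,nachr,-148.66,34.2,0
1800,cht,-224.29,94.04,0
1804,ache,-120.62,40.87,0
1804,nachr,-135.97,31.15,0
1804,cht,-219.43,113.8,0
1809,ache,-223.77,35.86,0
1809,nachr,-138.22,21.23,0
1809,cht,-176.35,170.0,0
1836,ache,-217.92,42.24,0
1836,nachr,-162.71,23.48,0
1836,cht,-240.23,127.8,0
1840,ache,-108.98,42.4,0
1840,nachr,-111.3,25.73,0
1840,cht,-219.83,142.0,0
1842,ache,-162.09,60.92,0
1842,nachr,-140.75,32.9,0
1842,cht,-181.34,45.7,0
1845,ache,-149.98,44.7,0
1845,nachr,-129.73,32.3,0
1845,cht,-179.35,120.2,0
1854,ache,-162.01,41.3,0
1854,nachr,-139.78,32.0,0
1854,cht,-194.6,71.5,0
1855,ache,-148.07,35.71,0
1855,nachr,-107.61,27.91,0
1855,cht,-170.44,76.3,0
1910,ache,-126.98,33.08,0
1910,nachr,-148.83,33.24,0
1910,cht,-198.84,77.8,0
1931,ache,-180.5,45.2,0
1931,nachr,-140.9,36.38,0
1931,cht,-197.69,99.8,0
1932,ache,-149.64,45.07,0
1932,nachr,-141.42,29.28,0
1932,cht,-183.22,92.2,0
1933,ache,-142.05,32.84,0
1933,nachr,-147.59,30.35,0
1933,cht,-191.2,79.4,0
1934,ache,-154.26,41.82,0
1934,nachr,-89.66,30.02,0
1934,cht,-195.89,125.7,0
1936,ache,-172.98,28.17,0
1936,nachr,-139.01,32.95,0
1936,cht,-206.48,63.9,0
chlorpyrifos,ache,-88.38,29.34,1
clothianidin,nachr,-55.89,39.26,1
allosamidin,cht,-146.23,62.0,1
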