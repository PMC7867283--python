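compound_id,enzyme_id,prob_comb,p_activity
1800,ache,0.7,0.61
1800,nachr,0.74,0.61
1800,cht,0.7,0.61
1804,ache,0.64,0.66
1804,nachr,0.74,0.66
1804,cht,0.75,0.66
1809,ache,0.75,0.61
1809,nachr,0.7,0.61
1809,cht,0.73,0.61
1836,ache,0.76,0.62
1836,nachr,0.76,0.62
1836,cht,0.76,0.62
1840,ache,0.63,0.66
1840,nachr,0.68,0.66
1840,cht,0.78,0.66
1842,ache,0.73,0.66
1842,nachr,0.76,0.66
1842,cht,0.64,0.66
1845,ache,0.68,0.65
1845,nachr,0.73,0.65
1845,cht,0.71,0.65
1854,ache,0.64,0.57
1854,nachr,0.7,0.57
1854,cht,0.62,0.57
1855,ache,0.62,0.58
1855,nachr,0.63,0.58
1855,cht,0.61,0.58
1910,ache,0.59,0.58
1910,nachr,0.72,0.58
1910,cht,0.64,0.58
1931,ache,0.73,0.66
1931,nachr,0.76,0.66
1931,cht,0.71,0.66
1932,ache,0.68,0.64
1932,nachr,0.74,0.64
1932,cht,0.68,0.64
1933,ache,0.64,0.63
1933,nachr,0.75,0.63
1933,cht,0.66,0.63
1934,ache,0.7,0.67
1934,nachr,0.65,0.67
1934,cht,0.74,0.67
1936,ache,0.7,0.67
1936,nachr,0.76,0.67
1936,cht,0.69,0.67
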