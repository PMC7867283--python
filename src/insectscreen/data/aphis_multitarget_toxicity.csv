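compound_id,mutagenic,tumorigenic,reproductive_effective,irritant
1800,No,No,No,No
1804,No,No,No,No
1809,No,No,No,High
1836,No,No,No,No
1840,No,No,No,No
1842,No,No,No,No
1845,No,No,No,No
1854,No,No,No,High
1855,No,No,No,High
1910,No,No,No,No
1931,No,No,No,No
1932,No,No,No,No
1933,No,No,No,No
1934,No,No,No,No
1936,High,High,None,High
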