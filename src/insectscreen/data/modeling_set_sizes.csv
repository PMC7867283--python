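species,n_active,n_inactive,plc50_threshold
aphis,91,75,4.5
drosophila,105,103,4.5
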