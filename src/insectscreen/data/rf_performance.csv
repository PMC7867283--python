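species,validation,accuracy,sensitivity,specificity,ppv,npv,mcc
aphis,test,0.74,0.76,0.76,0.76,0.76,0.52
aphis,cross,0.7,0.73,0.67,0.7,0.7,0.4
drosophila,test,0.76,0.76,0.76,0.76,0.76,0.52
drosophila,cross,0.73,0.76,0.71,0.73,0.74,0.47
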