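model,setting,mae,rmse
MCNN,full,30.76,31.12
CSR-net,full,6.50,27.06
DM-Count,full,6.84,12.85
SPSC-net,full,2.27,7.00
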