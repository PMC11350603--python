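model,setting,mae,rmse
base,50%,63.92,78.25
base+MDC,50%,48.54,63.07
base+AFF,50%,12.32,18.36
base+AFF+MDC,50%,8.78,16.60
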