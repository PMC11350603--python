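model,setting,mae,rmse
Dream,5%,103.63,135.48
Calibrating,5%,37.28,47.32
MTCP,5%,32.74,44.13
DACount,5%,21.45,30.31
MRC,5%,19.48,27.95
MTSC-Net,5%,17.71,25.49
Dream,10%,81.97,99.11
Calibrating,10%,31.44,39.64
MTCP,10%,29.41,37.80
DACount,10%,20.51,26.48
MRC,10%,18.77,24.19
MTSC-Net,10%,16.24,20.68
Dream,20%,44.62,51.40
Calibrating,20%,26.14,30.78
MTCP,20%,22.59,28.35
DACount,20%,20.24,26.77
MRC,20%,15.35,21.68
MTSC-Net,20%,11.28,17.30
Dream,30%,26.42,33.52
Calibrating,30%,24.56,30.40
MTCP,30%,19.75,27.62
DACount,30%,17.67,24.28
MRC,30%,13.79,18.78
MTSC-Net,30%,10.20,17.98
Dream,40%,23.93,31.38
Calibrating,40%,21.88,28.02
MTCP,40%,16.55,21.23
DACount,40%,16.93,22.04
MRC,40%,12.21,17.32
MTSC-Net,40%,9.73,16.64
Dream,50%,19.91,25.42
Calibrating,50%,20.91,27.34
MTCP,50%,14.42,18.08
DACount,50%,8.91,17.62
MRC,50%,10.48,15.69
MTSC-Net,50%,8.78,16.60
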