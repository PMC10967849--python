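pred,L-HS,R-TO,R-HMax,R-HS,L-TO,L-HMax
L-HS,0.975,0,0,0,0,0.017
R-TO,0.010,0.995,0,0,0,0
R-HMax,0,0.005,0.991,0.010,0,0
R-HS,0,0,0.009,0.970,0,0
L-TO,0,0,0,0.020,0.991,0
L-HMax,0.015,0,0,0,0.009,0.983
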