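pred,SD,LW,US,DS,USL,DSL,TL,TR,LS,RS
SD,0.99,0,0,0,0,0,0,0,0,0
LW,0,1.00,0,0,0,0,0,0,0,0
US,0,0,1.00,0,0,0,0,0,0,0
DS,0,0,0,1.00,0,0,0,0,0,0
USL,0,0,0,0,1.00,0,0,0,0,0
DSL,0,0,0,0,0,1.00,0,0,0,0
TL,0,0,0,0,0,0,1.00,0,0,0
TR,0,0,0,0,0,0,0,1.00,0,0
LS,0.01,0,0,0,0,0,0,0,0.99,0
RS,0,0,0,0,0,0,0,0,0.01,1.00
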