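lead,tp,fn,fp
i,159,0,0
ii,159,0,0
iii,159,0,0
avr,159,0,0
avl,159,0,0
avf,158,3,21
v1,159,0,0
v2,159,0,0
v3,159,0,0
v4,158,1,0
v5,159,0,0
v6,159,0,0
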