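id,logp,mw,hba,hbd
M1,6.86,476.50,7,0
M2,6.71,476.51,8,0
M6,6.47,492.50,8,1
M9,5.90,488.50,8,1
M10,4.40,476.49,8,3
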