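id,caco2,hia,logbb,logps,cyp2d6_inhibitor,total_clearance,ames_toxic,ld50,hepatotoxic,skin_sensitizer
M1,1.039,91.194,0.39,-1.292,No,0.336,No,2.553,No,No
M2,1.108,92.923,0.001,-1.371,No,0.261,No,2.752,No,No
M6,1.025,88.775,0.12,-1.56,No,0.214,No,2.366,No,No
M9,0.457,91.153,-0.96,-1.692,No,0.239,No,2.964,No,No
M10,0.947,88.76,-1.299,-2.193,No,0.647,No,2.85,Yes,No
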