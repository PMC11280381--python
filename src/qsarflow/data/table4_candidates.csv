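id,DM,PSA,MW,pic50_printed,leverage_printed,domain_printed
M1,3.599,27.690,476.510,7.49,0.106,Inside
M2,3.678,43.180,476.510,7.36,0.058,Inside
M3,3.291,63.410,460.500,7.01,,
M4,3.811,63.410,460.500,7.11,,
M5,2.125,27.690,458.520,7.13,,
M6,2.721,47.920,492.510,7.27,0.080,Inside
M7,3.239,88.380,478.460,6.92,,
M8,2.110,47.920,474.520,7.07,,
M9,4.230,64.990,488.500,7.36,0.054,Inside
M10,5.186,74.190,476.490,7.34,0.060,Inside
M11,5.080,94.420,478.468,7.15,0.138,Inside
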