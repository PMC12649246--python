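scan_id,frozen_mm3,thawed_mm3
1,1254.32,1257.79
2,1253.31,1258.09
3,1261.33,1268.16
4,1265.97,1258.51
5,1273.02,1258.25
6,1249.78,1257.63
7,1259.22,1259.96
8,1246.46,1252.37
9,1253.58,1259.31
10,1257.34,1262.01
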