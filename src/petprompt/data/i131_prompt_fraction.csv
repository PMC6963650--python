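activity_uci,350-650,350-750,450-650,450-750
1,0.00,0.00,0.00,0.00
10,0.01,0.01,0.00,0.00
100,1.45,1.60,0.00,0.00
200,5.59,5.88,0.00,0.01
300,11.64,12.25,0.00,0.02
400,19.70,18.65,0.00,0.04
500,27.85,26.53,0.01,0.05
600,35.31,33.92,0.01,0.07
700,42.53,41.12,0.01,0.09
800,49.08,47.54,0.01,0.12
900,54.81,53.30,0.02,0.17
1000,58.50,59.74,0.02,0.21
10000,98.96,99.01,1.28,18.48
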