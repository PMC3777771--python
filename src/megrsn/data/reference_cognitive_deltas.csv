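subject,overall,executive_functioning,verbal_memory,working_memory,information_processing,attention,psychomotor_speed
1,0.45,-0.28,-0.05,0.20,0.47,2.59,0.45
2,-0.06,-0.39,-0.38,0.14,-0.23,0.18,-0.59
3,-0.09,-0.28,-0.03,-0.36,-0.17,0.14,0.56
4,-0.79,-0.40,-2.15,-0.17,-0.01,-0.23,0.16
5,,,,,,,
6,-0.02,-0.51,0.35,0.06,0.57,-0.29,-0.86
7,,,,,,,
8,-1.33,-1.65,-1.00,-1.02,-1.07,-2.88,-0.15
9,-0.09,0.29,-0.04,-0.09,0.08,0.09,-0.11
10,0.34,-0.14,0.35,0.12,0.43,0.75,0.55
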