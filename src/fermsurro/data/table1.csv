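run,X1,X2,X3,X4,X5,Y1,Y2
N1,16,0.3,4.5,5,108,89.5686,0.05715
N2,17,1.4,10.5,9,168,76.9796,0.1079
N3,11,0.4,7.5,10,204,81.6116,0.08085
N4,19,1.5,8,4,96,81.0957,0.05875
N5,12,1.7,7,5.5,192,79.7349,0.12175
N6,15,1,9.5,4.5,228,84.5514,0.2283
N7,20,0.9,6.5,9.5,60,8.3172,0.03545
N8,9,0.8,6,3.5,156,12.5545,0.0001
N9,18,0.7,3.5,8,180,86.3218,0.11275
N10,8,1.1,8.5,8.5,120,84.6537,0.0412
N11,14,1.6,5,10.5,132,76.7769,0.04345
N12,21,1.2,5.5,7,216,74.7522,0.1718
N13,10,1.3,4,6.5,72,67.7670,0.02315
N14,13,0.6,10,7.5,84,77.7472,0.04345
N15,22,0.5,9,6,144,80.3603,0.12165
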