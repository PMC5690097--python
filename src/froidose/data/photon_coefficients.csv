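symbol,energy_kev,mu_over_rho,mu_en_over_rho
H,1,385.4,9.849
H,2,48.175,1.23113
H,3,14.2741,0.364778
H,4,6.02188,0.153891
H,5,3.0832,0.078792
H,6,1.78426,0.0455972
H,8,0.752734,0.0192363
H,10,0.3854,0.009849
H,15,0.3764,0.01102
H,20,0.3695,0.01355
H,30,0.357,0.01863
H,40,0.3458,0.02315
H,50,0.3355,0.02709
H,60,0.326,0.03053
H,80,0.3091,0.0362
H,100,0.2944,0.04063
H,150,0.2651,0.04813
C,1,2373,2078
C,2,296.625,259.75
C,3,87.8889,76.963
C,4,37.0781,32.4688
C,5,18.984,16.624
C,6,10.9861,9.62037
C,8,4.63477,4.05859
C,10,2.373,2.078
C,15,0.8071,0.5627
C,20,0.442,0.2238
C,30,0.2562,0.06614
C,40,0.2076,0.03343
C,50,0.1871,0.02397
C,60,0.1753,0.02098
C,80,0.161,0.02037
C,100,0.1514,0.02147
C,150,0.1347,0.02449
N,1,3879,4493.48
N,2,484.875,561.685
N,3,143.667,166.425
N,4,60.6094,70.2107
N,5,31.032,35.9479
N,6,17.9583,20.8032
N,8,7.57617,8.77634
N,10,3.879,4.49348
N,15,1.236,1.27012
N,20,0.6178,0.515056
N,30,0.3066,0.147886
N,40,0.2288,0.0662252
N,50,0.198,0.0400273
N,60,0.1817,0.0299084
N,80,0.1639,0.0238856
N,100,0.1529,0.0231599
N,150,0.1353,0.0249303
O,1,5952,5565.69
O,2,744,695.711
O,3,220.444,206.137
O,4,93,86.9639
O,5,47.616,44.5255
O,6,27.5556,25.7671
O,8,11.625,10.8705
O,10,5.952,5.56569
O,15,1.836,1.54573
O,20,0.8651,0.617929
O,30,0.3779,0.17297
O,40,0.2585,0.0753062
O,50,0.2132,0.0441376
O,60,0.1907,0.0320726
O,80,0.1678,0.0246811
O,100,0.1551,0.0235486
O,150,0.1361,0.0250583
S,1,50070,47000
S,2,6258.75,5875
S,3,1854.44,1740.74
S,4,782.344,734.375
S,5,400.56,376
S,6,231.806,217.593
S,8,97.793,91.7969
S,10,50.07,47
S,15,15.77,14.5
S,20,6.708,5.85
S,30,2.113,1.76
S,40,0.9795,0.747
S,50,0.555,0.38
S,60,0.3656,0.216
S,80,0.2303,0.0966
S,100,0.18,0.0587
S,150,0.1394,0.0355
Al,1,26230,25430
Al,2,3278.75,3178.75
Al,3,971.481,941.852
Al,4,409.844,397.344
Al,5,209.84,203.44
Al,6,121.435,117.731
Al,8,51.2305,49.668
Al,10,26.23,25.43
Al,15,7.955,7.487
Al,20,3.441,3.094
Al,30,1.128,0.8778
Al,40,0.5685,0.3601
Al,50,0.3681,0.184
Al,60,0.2778,0.1099
Al,80,0.2018,0.05511
Al,100,0.1704,0.03794
Al,150,0.1378,0.02827
Cu,1,215900,148400
Cu,2,26987.5,18550
Cu,3,7996.3,5496.3
Cu,4,3373.44,2318.75
Cu,5,1727.2,1187.2
Cu,6,999.537,687.037
Cu,8,421.68,289.844
Cu,10,215.9,148.4
Cu,15,74.05,57.88
Cu,20,33.79,27.88
Cu,30,10.92,9.349
Cu,40,4.862,4.163
Cu,50,2.613,2.192
Cu,60,1.593,1.29
Cu,80,0.763,0.5581
Cu,100,0.4584,0.2949
Cu,150,0.2217,0.1027
Gd,1,159000,120000
Gd,2,19875,15000
Gd,3,5888.89,4444.44
Gd,4,2484.38,1875
Gd,5,1272,960
Gd,6,736.111,555.556
Gd,8,310.547,234.375
Gd,10,159,120
Gd,15,53,40
Gd,20,24,18
Gd,30,8,5.6
Gd,40,3.6,2.4
Gd,50.23,2.1,1.4
Gd,50.24,11.1,4.6
Gd,60,7,3.8
Gd,80,3.3,2.1
Gd,100,1.9,1.3
Gd,150,0.7,0.55
W,1,96910,79000
W,2,12113.8,9875
W,3,3589.26,2925.93
W,4,1514.22,1234.38
W,5,775.28,632
W,6,448.657,365.741
W,8,189.277,154.297
W,10,96.91,79
W,10.2,95,77
W,10.21,205,130
W,11.53,150,100
W,11.55,172,112
W,12.09,152,100
W,12.11,166,108
W,15,139.3,95
W,20,65.73,48
W,30,22.73,17.7
W,40,10.67,8.4
W,50,5.949,4.6
W,60,3.713,2.8
W,69.52,2.552,1.9
W,69.53,11,4.5
W,80,7.81,3.6
W,100,4.438,2.3
W,150,1.581,1
Air,1,5120,4742
Air,2,640,592.75
Air,3,189.63,175.63
Air,4,80,74.0938
Air,5,40.96,37.936
Air,6,23.7037,21.9537
Air,8,10,9.26172
Air,10,5.12,4.742
Air,15,1.614,1.334
Air,20,0.7779,0.5389
Air,30,0.3538,0.1537
Air,40,0.2485,0.06833
Air,50,0.208,0.04098
Air,60,0.1875,0.03041
Air,80,0.1662,0.02407
Air,100,0.1541,0.02325
Air,150,0.1356,0.02496
Water,1,5329,4944
Water,2,666.125,618
Water,3,197.37,183.111
Water,4,83.2656,77.25
Water,5,42.632,39.552
Water,6,24.6713,22.8889
Water,8,10.4082,9.65625
Water,10,5.329,4.944
Water,15,1.673,1.374
Water,20,0.8096,0.5503
Water,30,0.3756,0.1557
Water,40,0.2683,0.06947
Water,50,0.2269,0.04223
Water,60,0.2059,0.0319
Water,80,0.1837,0.02597
Water,100,0.1707,0.02546
Water,150,0.1505,0.02764
SoftTissue,1,5367,4964
SoftTissue,2,670.875,620.5
SoftTissue,3,198.778,183.852
SoftTissue,4,83.8594,77.5625
SoftTissue,5,42.936,39.712
SoftTissue,6,24.8472,22.9815
SoftTissue,8,10.4824,9.69531
SoftTissue,10,5.367,4.964
SoftTissue,15,1.693,1.396
SoftTissue,20,0.8205,0.5638
SoftTissue,30,0.3783,0.161
SoftTissue,40,0.2699,0.07192
SoftTissue,50,0.2276,0.04349
SoftTissue,60,0.2059,0.03258
SoftTissue,80,0.1837,0.02615
SoftTissue,100,0.1707,0.02544
SoftTissue,150,0.1505,0.02745
CorticalBone,1,28510,26800
CorticalBone,2,3563.75,3350
CorticalBone,3,1055.93,992.593
CorticalBone,4,445.469,418.75
CorticalBone,5,228.08,214.4
CorticalBone,6,131.991,124.074
CorticalBone,8,55.6836,52.3438
CorticalBone,10,28.51,26.8
CorticalBone,15,9.032,8.388
CorticalBone,20,4.001,3.601
CorticalBone,30,1.331,1.07
CorticalBone,40,0.6655,0.4507
CorticalBone,50,0.4242,0.2336
CorticalBone,60,0.3148,0.14
CorticalBone,80,0.2229,0.06896
CorticalBone,100,0.1855,0.04585
CorticalBone,150,0.148,0.03183
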