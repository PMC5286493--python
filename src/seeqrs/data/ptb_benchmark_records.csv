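case,tp,fn,fp,der,se,pp,acc
s0010_rem,624,0,0,0.000,100.000,100.000,100.000
s0014lrem,1987,0,0,0.000,100.000,100.000,100.000
s0015lrem,1815,0,2,0.110,100.000,99.890,99.890
s0017lrem,1673,0,5,0.299,100.000,99.702,99.702
s0020arem,1906,4,21,1.312,99.791,98.910,98.705
s0020brem,1867,5,20,1.339,99.733,98.940,98.679
s0021arem,2207,1,0,0.045,99.955,100.000,99.955
s0021brem,2196,0,0,0.000,100.000,100.000,100.000
s0025lrem,2382,6,0,0.252,99.749,100.000,99.749
s0029lrem,1638,0,0,0.000,100.000,100.000,100.000
s0031lrem,2111,1,0,0.047,99.953,100.000,99.953
s0035_rem,552,0,0,0.000,100.000,100.000,100.000
s0036lrem,2066,0,2,0.097,100.000,99.903,99.903
s0037lrem,1479,0,3,0.203,100.000,99.798,99.798
s0038lrem,1572,0,0,0.000,100.000,100.000,100.000
s0039lrem,2088,0,0,0.000,100.000,100.000,100.000
s0042lrem,1815,0,0,0.000,100.000,100.000,100.000
s0043lrem,1212,0,0,0.000,100.000,100.000,100.000
s0044lrem,1812,0,0,0.000,100.000,100.000,100.000
s0045lrem,1968,0,0,0.000,100.000,100.000,100.000
s0046lrem,1944,0,0,0.000,100.000,100.000,100.000
s0047lrem,2651,1,0,0.038,99.962,100.000,99.962
s0049lrem,2040,0,0,0.000,100.000,100.000,100.000
s0050lrem,1461,3,0,0.205,99.795,100.000,99.795
s0051lrem,1912,0,2,0.105,100.000,99.896,99.896
s0052lrem,1356,0,0,0.000,100.000,100.000,100.000
s0053lrem,2148,0,0,0.000,100.000,100.000,100.000
s0054lrem,1979,31,2,1.668,98.458,99.899,98.360
s0055lrem,1381,0,1,0.072,100.000,99.928,99.928
s0056lrem,1732,0,0,0.000,100.000,100.000,100.000
s0057lrem,1896,0,0,0.000,100.000,100.000,100.000
s0058lrem,2017,0,1,0.050,100.000,99.950,99.950
s0059lrem,1800,0,0,0.000,100.000,100.000,100.000
s0060lrem,140,0,0,0.000,100.000,100.000,100.000
s0062lrem,1488,0,0,0.000,100.000,100.000,100.000
s0063lrem,1845,3,0,0.163,99.838,100.000,99.838
s0064lrem,1797,3,0,0.167,99.833,100.000,99.833
s0065lrem,1704,0,0,0.000,100.000,100.000,100.000
s0066lrem,1513,0,1,0.066,100.000,99.934,99.934
s0067lrem,424,0,4,0.943,100.000,99.065,99.065
s0068lrem,1377,5,15,1.452,99.638,98.922,98.568
s0069lrem,1188,0,0,0.000,100.000,100.000,100.000
s0070lrem,1983,0,1,0.050,100.000,99.950,99.950
s0071lrem,1848,0,0,0.000,100.000,100.000,100.000
s0072lrem,2040,0,0,0.000,100.000,100.000,100.000
s0073lrem,2125,5,0,0.235,99.765,100.000,99.765
s0074lrem,1140,0,0,0.000,100.000,100.000,100.000
s0075lrem,1453,0,1,0.069,100.000,99.931,99.931
s0076lrem,1308,0,0,0.000,100.000,100.000,100.000
s0077lrem,1692,0,0,0.000,100.000,100.000,100.000
s0078lrem,1225,0,1,0.082,100.000,99.918,99.918
s0079lrem,1620,0,0,0.000,100.000,100.000,100.000
s0080lrem,1556,0,0,0.000,100.000,100.000,100.000
s0082lrem,1602,0,0,0.000,100.000,100.000,100.000
s0083lrem,1465,1,0,0.068,99.932,100.000,99.932
s0084lrem,1464,0,0,0.000,100.000,100.000,100.000
s0085lrem,1276,0,4,0.313,100.000,99.688,99.688
s0097lrem,2133,0,1,0.047,100.000,99.953,99.953
s0101lrem,1500,0,0,0.000,100.000,100.000,100.000
s0103lrem,1273,0,2,0.157,100.000,99.843,99.843
s0149lrem,1572,0,0,0.000,100.000,100.000,100.000
s0152lrem,1532,4,0,0.261,99.740,100.000,99.740
s0087lrem,1654,12,0,0.726,99.280,100.000,99.280
s0088lrem,1728,0,0,0.000,100.000,100.000,100.000
s0091lrem,1380,1,1,0.145,99.928,99.928,99.855
s0095lrem,1797,3,0,0.167,99.833,100.000,99.833
s0096lrem,2603,1,0,0.038,99.962,100.000,99.962
s0150lrem,1583,1,0,0.063,99.937,100.000,99.937
s0090lrem,1358,0,2,0.147,100.000,99.853,99.853
s0093lrem,1249,0,1,0.080,100.000,99.920,99.920
s0291lrem,1548,0,0,0.000,100.000,100.000,100.000
s0292lrem,1584,0,0,0.000,100.000,100.000,100.000
Total,119054,91,93,0.155,99.924,99.922,99.846
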