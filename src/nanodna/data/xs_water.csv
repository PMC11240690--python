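# simplified electron cross sections in liquid water
# sigma units: nm^2 per molecule; number density 33.3679 nm^-3
energy_ev,sigma_elastic,sigma_ionization,sigma_excitation
10,0.232451,0,0.00755286
11.3851,0.220908,0,0.0124576
12.9621,0.209088,0,0.0172953
14.7575,0.197082,0.00320604,0.0218452
16.8017,0.184989,0.00694802,0.0259631
19.1289,0.172909,0.0108092,0.0295596
21.7785,0.160944,0.0145531,0.0325841
24.7951,0.14919,0.0180237,0.0350155
28.2296,0.137737,0.0211213,0.0368545
32.1397,0.126667,0.0237861,0.0381194
36.5915,0.116048,0.0259876,0.0388418
41.6599,0.105937,0.0277166,0.039064
47.4304,0.0963762,0.0289804,0.0388359
54.0001,0.0873964,0.0297991,0.0382125
61.4798,0.0790146,0.0302026,0.0372515
69.9955,0.0712363,0.0302278,0.0360111
79.6908,0.064057,0.029917,0.0345481
90.7291,0.0574636,0.0293154,0.0329161
103.296,0.0514359,0.0284692,0.0311648
117.604,0.0459485,0.0274243,0.0293386
133.894,0.040972,0.0262246,0.0274763
152.44,0.0364744,0.024911,0.0256111
173.555,0.0324224,0.0235208,0.0237705
197.594,0.028782,0.0220866,0.0219767
224.964,0.0255198,0.0206369,0.0202468
256.124,0.022603,0.0191956,0.0185937
291.601,0.0200005,0.017782,0.0170263
331.991,0.0176825,0.0164115,0.0155504
377.976,0.0156212,0.0150959,0.0141689
430.331,0.0137909,0.0138436,0.0128826
489.938,0.0121678,0.0126604,0.0116904
557.8,0.01073,0.0115495,0.01059
635.063,0.00945767,0.0105125,0.00957795
723.028,0.00833273,0.00954917,0.00865018
823.176,0.00733889,0.00865815,0.0078021
937.197,0.00646149,0.00783721,0.00702884
1067.01,0.00568735,0.00708342,0.0063254
1214.81,0.0050047,0.00639337,0.00568678
1383.07,0.004403,0.00576338,0.00510807
1574.65,0.00387289,0.00518961,0.00458449
1792.76,0.003406,0.00466817,0.00411151
2041.08,0.00299495,0.00419518,0.0036848
2323.79,0.00263315,0.0037669,0.00330028
2645.67,0.00231479,0.0033797,0.00295418
3012.13,0.0020347,0.00303013,0.00264295
3429.35,0.00178834,0.00271492,0.00236334
3904.35,0.00157169,0.00243103,0.00211233
4445.16,0.00138118,0.00217561,0.00188718
5060.87,0.00121369,0.00194602,0.00168535
5761.87,0.00106645,0.00173982,0.00150454
6559.96,0.000937032,0.00155478,0.00134266
7468.6,0.000823283,0.00138885,0.00119781
8503.1,0.000723316,0.00124014,0.00106825
9680.89,0.000635466,0.00110696,0.00095243
11021.8,0.00055827,0.00098774,0.000848931
12548.5,0.000490439,0.000881081,0.000756482
14286.6,0.000430841,0.000785702,0.000673933
16265.5,0.000378477,0.000700449,0.00060025
18518.5,0.000332472,0.000624278,0.000534502
21083.5,0.000292055,0.000556248,0.000475854
24003.9,0.000256547,0.000495511,0.000423554
27328.7,0.000225354,0.000441304,0.000376927
31114.1,0.000197952,0.00039294,0.00033537
35423.9,0.00017388,0.000349803,0.00029834
40330.5,0.000152734,0.000311338,0.000265352
45916.8,0.000134159,0.000277048,0.000235971
52276.9,0.000117842,0.00024649,0.00020981
59517.9,0.000103509,0.000219262,0.000186519
67762,9.09193e-05,0.000195008,0.000165788
77147.9,7.98603e-05,0.000173408,0.00014734
87833.9,7.01462e-05,0.000154176,0.000130925
100000,6.16135e-05,0.000137055,0.000116323
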