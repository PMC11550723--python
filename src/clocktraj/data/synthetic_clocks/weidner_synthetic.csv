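cpg_id,coefficient
cg00000424,0.092419
cg00000425,-0.45017
cg00000426,0.124219
cg00000427,-0.081913
cg00000428,0.121903
cg00000429,0.383333
cg00000430,0.208359
cg00000431,-0.415337
cg00000432,0.565675
cg00000433,0.167068
cg00000434,0.167511
cg00000435,0.06957
cg00000436,-0.351426
cg00000437,0.158625
cg00000438,0.137513
cg00000439,-0.127306
cg00000440,0.135522
cg00000441,-0.47404
cg00000442,-0.002993
cg00000443,0.012724
cg00000444,0.016785
cg00000445,0.055513
cg00000446,0.159192
cg00000447,0.046777
cg00000448,0.000753
cg00000449,0.125484
cg00000450,-0.287221
cg00000451,-0.169684
cg00000452,0.023545
cg00000453,0.014439
cg00000454,-0.797903
cg00000455,0.119365
cg00000456,0.032884
cg00000457,-0.604424
cg00000458,0.140692
cg00000459,-0.177701
cg00000460,-0.647296
cg00000461,-0.306975
cg00000462,0.12456
cg00000463,0.040361
cg00000464,0.121014
cg00000465,0.135922
cg00000466,0.026508
cg00000467,0.037546
cg00000468,-0.134084
cg00000469,-0.059433
cg00000470,-0.007749
cg00000471,0.690019
cg00000472,-0.136367
cg00000473,0.117052
cg00000474,0.399499
cg00000475,-0.206679
cg00000476,0.406889
cg00000477,-0.053128
cg00000478,-0.199935
cg00000479,0.55597
cg00000480,-0.041685
cg00000481,-0.265194
cg00000482,0.042175
cg00000483,0.185408
cg00000484,0.176658
cg00000485,0.240431
cg00000486,-0.124034
cg00000487,0.06008
cg00000488,-0.240787
cg00000489,0.059019
cg00000490,-0.810995
cg00000491,0.177306
cg00000492,-0.06681
cg00000493,0.063637
cg00000494,0.03378
cg00000495,-0.026313
cg00000496,-0.206217
cg00000497,0.036468
cg00000498,0.033615
cg00000499,-0.109049
cg00000500,-0.461274
cg00000501,0.389156
cg00000502,-0.193074
cg00000503,0.086249
cg00000504,-0.044893
cg00000505,0.173998
cg00000506,0.528002
cg00000507,0.034797
cg00000508,0.441061
cg00000509,0.025438
cg00000510,-0.168102
cg00000511,0.077598
cg00000512,-0.287841
cg00000513,0.086887
cg00000514,0.321295
cg00000515,0.140985
cg00000516,-0.360641
cg00000517,0.080517
cg00000518,-0.227506
cg00000519,-0.876531
cg00000520,-0.188884
cg00000521,0.550906
cg00000522,-0.404165
cg00000523,-0.205449
cg00000524,0.183493
cg00000525,0.323182
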