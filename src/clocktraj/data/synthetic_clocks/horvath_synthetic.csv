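cpg_id,coefficient
cg00000000,0.141733
cg00000001,-0.679954
cg00000002,0.128677
cg00000003,-0.232423
cg00000004,0.069715
cg00000005,-0.131991
cg00000006,0.128152
cg00000007,-0.296514
cg00000008,0.081875
cg00000009,0.328954
cg00000010,0.187333
cg00000011,0.009018
cg00000012,0.415124
cg00000013,-0.639738
cg00000014,-0.811936
cg00000015,0.007119
cg00000016,0.213538
cg00000017,-0.127504
cg00000018,0.071099
cg00000019,-0.288571
cg00000020,0.009171
cg00000021,-0.220307
cg00000022,0.096873
cg00000023,-0.243477
cg00000024,0.245285
cg00000025,-0.196702
cg00000026,0.400853
cg00000027,-0.479853
cg00000028,-0.463253
cg00000029,-0.036696
cg00000030,-0.26809
cg00000031,0.20428
cg00000032,-0.400805
cg00000033,-0.249886
cg00000034,-0.235061
cg00000035,0.568399
cg00000036,0.027373
cg00000037,-0.138069
cg00000038,-0.507742
cg00000039,-0.250302
cg00000040,0.119026
cg00000041,-0.056669
cg00000042,0.32494
cg00000043,-0.568645
cg00000044,-0.059172
cg00000045,0.363522
cg00000046,-0.247949
cg00000047,0.134284
cg00000048,-0.448393
cg00000049,0.056466
cg00000050,0.465142
cg00000051,0.000564
cg00000052,0.064926
cg00000053,0.309748
cg00000054,0.096979
cg00000055,0.596453
cg00000056,0.461007
cg00000057,-0.206498
cg00000058,-0.191184
cg00000059,-0.598412
cg00000060,-0.157323
cg00000061,0.205916
cg00000062,-0.358623
cg00000063,-0.227018
cg00000064,0.268113
cg00000065,0.033107
cg00000066,0.14893
cg00000067,-0.106442
cg00000068,-0.045634
cg00000069,0.673406
cg00000070,-0.312487
cg00000071,0.004479
cg00000072,-0.299513
cg00000073,-0.284611
cg00000074,0.128528
cg00000075,0.153324
cg00000076,0.160919
cg00000077,0.108375
cg00000078,-0.489761
cg00000079,0.030004
cg00000080,0.176743
cg00000081,-0.053275
cg00000082,0.563127
cg00000083,0.246503
cg00000084,-0.016064
cg00000085,0.06757
cg00000086,0.288225
cg00000087,0.078068
cg00000088,-0.28013
cg00000089,-0.076897
cg00000090,-0.078677
cg00000091,0.281304
cg00000092,0.230639
cg00000093,0.02291
cg00000094,-0.019649
cg00000095,0.174627
cg00000096,0.299759
cg00000097,0.036868
cg00000098,0.459357
cg00000099,0.077613
cg00000100,-0.340974
cg00000101,0.167442
cg00000102,-0.269194
cg00000103,0.031372
cg00000104,-0.006839
cg00000105,0.44087
cg00000106,0.416577
cg00000107,0.393229
cg00000108,0.002398
cg00000109,0.013239
cg00000110,-0.825588
cg00000111,-0.020182
cg00000112,0.141749
cg00000113,-0.047041
cg00000114,0.120219
cg00000115,0.215791
cg00000116,-0.217225
cg00000117,0.720786
cg00000118,-0.049341
cg00000119,0.035917
cg00000120,-0.205252
cg00000121,-0.490606
cg00000122,0.128602
cg00000123,-0.00694
cg00000124,0.00188
cg00000125,-0.04844
cg00000126,-0.207953
cg00000127,-0.085967
cg00000128,-0.280566
cg00000129,-0.236792
cg00000130,0.25979
cg00000131,-0.166602
cg00000132,-0.104609
cg00000133,-0.448503
cg00000134,0.146952
cg00000135,-0.11577
cg00000136,0.020167
cg00000137,-0.212708
cg00000138,-0.058497
cg00000139,0.183689
cg00000140,0.005127
cg00000141,-0.016413
cg00000142,-0.157888
cg00000143,0.261933
cg00000144,-0.13975
cg00000145,0.027303
cg00000146,-0.195382
cg00000147,0.377555
cg00000148,-0.070966
cg00000149,-0.466627
cg00000150,-0.151748
cg00000151,0.046774
cg00000152,0.182494
cg00000153,0.003509
cg00000154,-0.113076
cg00000155,-0.057579
cg00000156,0.75344
cg00000157,-0.16988
cg00000158,-0.26688
cg00000159,0.202043
cg00000160,-0.394732
cg00000161,-0.424406
cg00000162,0.298292
cg00000163,0.277894
cg00000164,0.122471
cg00000165,-0.372311
cg00000166,-0.490384
cg00000167,-0.082694
cg00000168,0.356706
cg00000169,0.207586
cg00000170,-0.324135
cg00000171,-0.051622
cg00000172,-0.162307
cg00000173,-0.094276
cg00000174,-0.181198
cg00000175,-0.372118
cg00000176,0.338899
cg00000177,-0.13733
cg00000178,0.218709
cg00000179,-0.735676
cg00000180,0.488791
cg00000181,0.408382
cg00000182,0.768021
cg00000183,-0.383687
cg00000184,-0.232871
cg00000185,0.394646
cg00000186,-0.252529
cg00000187,0.667785
cg00000188,0.242143
cg00000189,0.295325
cg00000190,-0.289548
cg00000191,-0.36445
cg00000192,-0.470798
cg00000193,0.518827
cg00000194,0.279453
cg00000195,-0.19535
cg00000196,0.078817
cg00000197,-0.012592
cg00000198,0.180871
cg00000199,0.030044
cg00000200,0.378384
cg00000201,0.427812
cg00000202,0.186597
cg00000203,-0.570199
cg00000204,-0.165848
cg00000205,-0.389188
cg00000206,0.099456
cg00000207,-0.03907
cg00000208,-0.016976
cg00000209,0.054376
cg00000210,-0.277114
cg00000211,0.093657
cg00000212,0.121938
cg00000213,-0.137854
cg00000214,-0.484493
cg00000215,0.25749
cg00000216,-0.387795
cg00000217,0.326368
cg00000218,0.218543
cg00000219,0.03684
cg00000220,-0.162019
cg00000221,-0.046612
cg00000222,-0.057957
cg00000223,-0.408978
cg00000224,0.158331
cg00000225,0.061167
cg00000226,-0.413961
cg00000227,0.114659
cg00000228,-0.369715
cg00000229,0.257275
cg00000230,0.025262
cg00000231,0.236427
cg00000232,0.071807
cg00000233,-0.390722
cg00000234,0.433831
cg00000235,0.466247
cg00000236,-0.054022
cg00000237,0.066713
cg00000238,-0.191537
cg00000239,0.157663
cg00000240,-0.022919
cg00000241,0.509445
cg00000242,0.341486
cg00000243,-0.13995
cg00000244,-0.332224
cg00000245,0.137725
cg00000246,-0.035326
cg00000247,-0.009484
cg00000248,-0.187921
cg00000249,-0.309195
cg00000250,-0.274142
cg00000251,0.073107
cg00000252,0.047041
cg00000253,0.067635
cg00000254,-0.498677
cg00000255,0.317144
cg00000256,0.10515
cg00000257,-0.196078
cg00000258,-0.217303
cg00000259,0.129033
cg00000260,-0.050982
cg00000261,-0.183863
cg00000262,0.102399
cg00000263,-0.148744
cg00000264,-0.271942
cg00000265,0.101366
cg00000266,-0.672271
cg00000267,0.324316
cg00000268,0.094005
cg00000269,-0.378595
cg00000270,0.155319
cg00000271,0.228569
cg00000272,0.178169
cg00000273,-0.161342
cg00000274,0.37232
cg00000275,0.127181
cg00000276,0.370698
cg00000277,0.087906
cg00000278,-0.405097
cg00000279,0.042281
cg00000280,-0.332387
cg00000281,0.178566
cg00000282,-0.235111
cg00000283,0.111239
cg00000284,0.111194
cg00000285,0.422986
cg00000286,0.155732
cg00000287,-0.146869
cg00000288,0.140405
cg00000289,0.176692
cg00000290,0.243547
cg00000291,-0.120533
cg00000292,0.217375
cg00000293,-0.023588
cg00000294,0.287206
cg00000295,-0.300801
cg00000296,-0.055539
cg00000297,-0.181245
cg00000298,-0.069921
cg00000299,-0.148916
cg00000300,-0.553477
cg00000301,0.051081
cg00000302,-0.105544
cg00000303,-0.096108
cg00000304,-0.065756
cg00000305,0.01074
cg00000306,0.513078
cg00000307,0.139948
cg00000308,-0.248407
cg00000309,0.194396
cg00000310,-0.205205
cg00000311,-0.274508
cg00000312,0.231228
cg00000313,0.298834
cg00000314,-0.113851
cg00000315,-0.279335
cg00000316,0.291995
cg00000317,0.119612
cg00000318,-0.214789
cg00000319,-0.207679
cg00000320,-0.541904
cg00000321,0.487983
cg00000322,0.007253
cg00000323,-0.218793
cg00000324,0.300655
cg00000325,0.039428
cg00000326,0.228319
cg00000327,-0.777607
cg00000328,-0.493005
cg00000329,0.418352
cg00000330,-0.336044
cg00000331,0.129337
cg00000332,-0.205473
cg00000333,0.058646
cg00000334,-0.00989
cg00000335,0.727192
cg00000336,-0.12504
cg00000337,0.635175
cg00000338,0.122964
cg00000339,0.260909
cg00000340,-0.197493
cg00000341,0.040547
cg00000342,0.525873
cg00000343,0.559463
cg00000344,-0.311114
cg00000345,-0.217397
cg00000346,-0.358926
cg00000347,-0.235366
cg00000348,-0.35288
cg00000349,0.111594
cg00000350,0.382613
cg00000351,0.773473
cg00000352,0.53847
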