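cpg_id,coefficient
cg00001605,0.026533
cg00001606,-0.157602
cg00001607,0.035413
cg00001608,0.132887
cg00001609,-0.390862
cg00001610,0.10429
cg00001611,0.01829
cg00001612,0.32885
cg00001613,0.099964
cg00001614,-0.516875
cg00001615,-0.499923
cg00001616,0.430337
cg00001617,-0.04416
cg00001618,-0.129963
cg00001619,-0.403907
cg00001620,-0.246777
cg00001621,-0.387477
cg00001622,0.027761
cg00001623,0.101575
cg00001624,-0.559279
cg00001625,-0.018192
cg00001626,0.146766
cg00001627,0.248281
cg00001628,-0.221831
cg00001629,0.120332
cg00001630,0.035871
cg00001631,0.647297
cg00001632,0.059162
cg00001633,-0.277497
cg00001634,0.079101
cg00001635,0.315921
cg00001636,-0.385649
cg00001637,-0.048727
cg00001638,-0.256072
cg00001639,-0.365867
cg00001640,-0.033975
cg00001641,0.758581
cg00001642,0.239017
cg00001643,-0.219122
cg00001644,0.361173
cg00001645,0.256613
cg00001646,-0.006197
cg00001647,-0.358231
cg00001648,0.871117
cg00001649,-0.206354
cg00001650,0.144758
cg00001651,0.121277
cg00001652,0.208481
cg00001653,0.325896
cg00001654,-0.091145
cg00001655,0.321498
cg00001656,0.09128
cg00001657,-0.207872
cg00001658,0.072414
cg00001659,-0.158502
cg00001660,-0.1571
cg00001661,-0.156101
cg00001662,0.228635
cg00001663,0.390456
cg00001664,-0.000133
cg00001665,-0.570348
cg00001666,-0.638302
cg00001667,-0.283703
cg00001668,0.29051
cg00001669,0.011811
cg00001670,-0.196686
cg00001671,0.069157
cg00001672,-0.23659
cg00001673,0.186669
cg00001674,0.293034
cg00001675,-0.088769
cg00001676,0.759516
cg00001677,-0.224584
cg00001678,0.510965
cg00001679,-0.091551
cg00001680,0.101051
cg00001681,0.011566
cg00001682,-0.327374
cg00001683,-0.458857
cg00001684,-0.276958
cg00001685,-0.008746
cg00001686,0.358689
cg00001687,0.068908
cg00001688,0.52484
cg00001689,-0.017979
cg00001690,0.047841
cg00001691,0.202667
cg00001692,-0.252393
cg00001693,-0.294781
cg00001694,-0.200145
cg00001695,-0.435549
cg00001696,-0.459683
cg00001697,-0.670219
cg00001698,0.059935
cg00001699,0.008448
cg00001700,0.131611
cg00001701,-0.029682
cg00001702,-0.482233
cg00001703,-0.627293
cg00001704,0.043371
cg00001705,0.254029
cg00001706,0.564085
cg00001707,0.105991
cg00001708,0.077946
cg00001709,0.316421
cg00001710,0.269495
cg00001711,0.125456
cg00001712,0.163129
cg00001713,-0.543732
cg00001714,-0.023512
cg00001715,0.043101
cg00001716,0.349343
cg00001717,-0.044859
cg00001718,0.120432
cg00001719,-0.602703
cg00001720,-0.17923
cg00001721,0.373017
cg00001722,0.426618
cg00001723,-0.30442
cg00001724,0.083104
cg00001725,0.332699
cg00001726,-0.20228
cg00001727,0.226456
cg00001728,-0.321178
cg00001729,-0.716805
cg00001730,0.146435
cg00001731,-0.289285
cg00001732,0.068133
cg00001733,0.181788
cg00001734,0.081231
cg00001735,0.082044
cg00001736,-0.312211
cg00001737,-0.329746
cg00001738,0.025647
cg00001739,-0.005747
cg00001740,0.417157
cg00001741,-0.120007
cg00001742,-0.141701
cg00001743,-0.259815
cg00001744,-0.225619
cg00001745,-0.067947
cg00001746,-0.372027
cg00001747,-0.164216
cg00001748,0.177996
cg00001749,-0.691918
cg00001750,0.234498
cg00001751,-0.14636
cg00001752,-0.018311
cg00001753,-0.221468
cg00001754,-0.471077
cg00001755,-0.212647
cg00001756,-0.476128
cg00001757,0.173822
cg00001758,-0.0318
cg00001759,0.11467
cg00001760,-0.293076
cg00001761,0.184182
cg00001762,0.264612
cg00001763,0.020644
cg00001764,0.309146
cg00001765,-0.57408
cg00001766,0.184782
cg00001767,0.51179
cg00001768,-0.072877
cg00001769,-0.428307
cg00001770,-0.109465
cg00001771,0.409976
cg00001772,-0.295902
cg00001773,0.144865
cg00001774,-0.333885
cg00001775,0.213713
cg00001776,0.158018
cg00001777,-0.249828
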