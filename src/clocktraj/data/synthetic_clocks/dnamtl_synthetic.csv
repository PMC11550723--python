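cpg_id,coefficient
cg00001157,-0.295718
cg00001158,-0.374268
cg00001159,-0.171213
cg00001160,-0.383964
cg00001161,-0.284534
cg00001470,-0.299833
cg00001471,-0.122127
cg00001472,-0.023475
cg00001473,-0.211882
cg00001474,-0.441824
cg00001475,-0.039876
cg00001476,-0.307411
cg00001477,-0.229227
cg00001478,-0.146519
cg00001479,-0.126773
cg00001480,-0.189361
cg00001481,-0.062085
cg00001482,-0.07913
cg00001483,-0.279582
cg00001484,-0.619236
cg00001485,-0.145511
cg00001486,-0.648519
cg00001487,-0.06617
cg00001488,-0.031394
cg00001489,-0.011478
cg00001490,-0.175727
cg00001491,-0.189721
cg00001492,-0.164898
cg00001493,-0.176199
cg00001494,-0.262478
cg00001495,-0.02692
cg00001496,-0.473222
cg00001497,-0.05641
cg00001498,-0.20285
cg00001499,-0.423348
cg00001500,-0.163169
cg00001501,-0.343695
cg00001502,-0.162638
cg00001503,-0.467948
cg00001504,-0.16921
cg00001505,-0.212798
cg00001506,-0.512442
cg00001507,-0.195125
cg00001508,-0.194579
cg00001509,-0.204526
cg00001510,-0.28454
cg00001511,-0.178255
cg00001512,-0.109884
cg00001513,-0.074834
cg00001514,-0.656684
cg00001515,-0.219743
cg00001516,-0.157839
cg00001517,-0.501075
cg00001518,-0.311186
cg00001519,-0.148377
cg00001520,-0.064902
cg00001521,-0.081474
cg00001522,-0.195971
cg00001523,-0.343088
cg00001524,-0.085495
cg00001525,-0.252137
cg00001526,-0.373746
cg00001527,-0.315859
cg00001528,-0.475085
cg00001529,-0.01189
cg00001530,-0.484369
cg00001531,-0.186529
cg00001532,-0.26362
cg00001533,-0.378666
cg00001534,-0.111588
cg00001535,-0.37576
cg00001536,-0.309999
cg00001537,-0.0187
cg00001538,-0.464765
cg00001539,-0.272674
cg00001540,-0.47402
cg00001541,-0.039374
cg00001542,-0.08986
cg00001543,-0.228118
cg00001544,-0.471068
cg00001545,-0.473985
cg00001546,-0.163392
cg00001547,-0.000641
cg00001548,-0.350589
cg00001549,-0.462573
cg00001550,-0.012041
cg00001551,-0.094148
cg00001552,-0.280654
cg00001553,-0.159258
cg00001554,-0.075956
cg00001555,-0.145268
cg00001556,-0.015269
cg00001557,-0.485233
cg00001558,-0.343732
cg00001559,-0.071646
cg00001560,-0.197099
cg00001561,-0.529415
cg00001562,-0.066201
cg00001563,-0.350186
cg00001564,-0.003672
cg00001565,-0.389731
cg00001566,-0.077178
cg00001567,-0.559448
cg00001568,-0.423896
cg00001569,-0.626864
cg00001570,-0.014646
cg00001571,-0.179252
cg00001572,-0.087004
cg00001573,-0.123738
cg00001574,-0.275794
cg00001575,-0.083089
cg00001576,-0.194584
cg00001577,-0.19315
cg00001578,-0.045592
cg00001579,-0.376776
cg00001580,-0.570943
cg00001581,-0.581877
cg00001582,-0.175589
cg00001583,-0.480253
cg00001584,-0.491615
cg00001585,-0.325096
cg00001586,-0.100718
cg00001587,-0.000663
cg00001588,-0.098534
cg00001589,-0.062619
cg00001590,-0.500893
cg00001591,-0.066183
cg00001592,-0.029715
cg00001593,-0.618983
cg00001594,-0.066301
cg00001595,-0.110704
cg00001596,-0.44038
cg00001597,-0.797332
cg00001598,-0.24317
cg00001599,-0.159574
cg00001600,-0.148682
cg00001601,-0.478449
cg00001602,-0.198624
cg00001603,-0.484542
cg00001604,-0.107485
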