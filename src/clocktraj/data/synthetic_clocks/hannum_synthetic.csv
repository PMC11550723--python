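cpg_id,coefficient
cg00000353,-0.27877
cg00000354,0.183361
cg00000355,-0.039386
cg00000356,0.541247
cg00000357,0.044613
cg00000358,0.57556
cg00000359,-0.223341
cg00000360,0.414964
cg00000361,-0.4134
cg00000362,0.142026
cg00000363,0.341015
cg00000364,-0.105068
cg00000365,0.196851
cg00000366,-0.323795
cg00000367,0.379344
cg00000368,-0.32062
cg00000369,0.204373
cg00000370,-0.145601
cg00000371,0.16405
cg00000372,-0.098773
cg00000373,0.12539
cg00000374,-0.130988
cg00000375,-0.04128
cg00000376,0.009345
cg00000377,-0.265107
cg00000378,-0.184401
cg00000379,-0.130415
cg00000380,-0.563282
cg00000381,-0.08469
cg00000382,-0.298548
cg00000383,0.204052
cg00000384,-0.074476
cg00000385,-0.721129
cg00000386,-0.169614
cg00000387,-0.037161
cg00000388,0.031883
cg00000389,0.326923
cg00000390,-0.091641
cg00000391,-0.327941
cg00000392,0.142707
cg00000393,-0.494798
cg00000394,0.191622
cg00000395,0.480776
cg00000396,0.026546
cg00000397,0.227053
cg00000398,0.177032
cg00000399,-0.442936
cg00000400,-0.215833
cg00000401,-0.137255
cg00000402,-0.35904
cg00000403,0.183107
cg00000404,-0.47677
cg00000405,0.412091
cg00000406,-0.120072
cg00000407,0.380233
cg00000408,0.632028
cg00000409,0.186831
cg00000410,-0.165646
cg00000411,-0.203873
cg00000412,0.040198
cg00000413,0.004987
cg00000414,-0.254332
cg00000415,-0.535756
cg00000416,-0.576686
cg00000417,-0.119907
cg00000418,0.135287
cg00000419,0.067809
cg00000420,-0.562194
cg00000421,0.012641
cg00000422,0.061235
cg00000423,-0.405628
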