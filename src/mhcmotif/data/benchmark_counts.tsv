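allele	length	all	binders
H-2-Db	9	1204	263
H-2-Dd	9	201	13
H-2-Kd	9	298	126
H-2-Kk	9	164	78
HLA-A*0201	9	3319	1392
HLA-A*3001	9	641	351
HLA-A*3201	9	573	275
HLA-A*6802	9	2223	562
HLA-B*0702	9	675	211
HLA-B*0801	9	608	297
HLA-B*1501	9	668	388
HLA-B*1503	9	496	348
HLA-B*2705	9	435	155
HLA-B*3501	9	560	155
HLA-B*5101	9	539	83
HLA-B*5301	9	539	161
HLA-B*5401	9	539	91
HLA-B*5801	9	278	66
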