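pdb,category,aspdock_hits,srm_hits
1acb,enzyme_inhibitor,3,7
1avx,enzyme_inhibitor,0,7
1ay7,enzyme_inhibitor,22,233
1bvn,enzyme_inhibitor,60,163
1cgi,enzyme_inhibitor,23,117
1d6r,enzyme_inhibitor,11,7
1dfj,enzyme_inhibitor,1,50
1e6e,enzyme_inhibitor,43,24
1eaw,enzyme_inhibitor,20,233
1ewy,enzyme_inhibitor,94,212
1ezu,enzyme_inhibitor,0,0
1f34,enzyme_inhibitor,8,10
1fq1,enzyme_inhibitor,0,0
1hia,enzyme_inhibitor,53,115
1ijk,enzyme_inhibitor,0,0
1kkl,enzyme_inhibitor,0,1
1m10,enzyme_inhibitor,0,0
1mah,enzyme_inhibitor,1,2
1n8o,enzyme_inhibitor,1,55
1nw9,enzyme_inhibitor,7,16
1oph,enzyme_inhibitor,0,0
1ppe,enzyme_inhibitor,310,461
1pxv,enzyme_inhibitor,0,0
1r0r,enzyme_inhibitor,13,132
1tmq,enzyme_inhibitor,5,72
1udi,enzyme_inhibitor,28,248
1yvb,enzyme_inhibitor,11,93
2b42,enzyme_inhibitor,0,0
2mta,enzyme_inhibitor,12,19
2o8v,enzyme_inhibitor,0,0
2pcc,enzyme_inhibitor,0,15
2sic,enzyme_inhibitor,1,0
2sni,enzyme_inhibitor,7,26
2uuy,enzyme_inhibitor,1,0
7cei,enzyme_inhibitor,7,30
1a2k,other,0,0
1ak4,other,0,0
1akj,other,21,8
1atn,other,0,0
1azs,other,0,0
1b6c,other,4,28
1bkd,other,0,0
1buh,other,36,2
1de4,other,0,0
1e96,other,3,14
1eer,other,0,14
1efn,other,1,5
1f51,other,27,18
1fak,other,0,0
1fc2,other,0,0
1fqj,other,2,69
1gcq,other,1,83
1ghq,other,0,0
1gla,other,0,0
1gp2,other,0,0
1gpw,other,11,71
1grn,other,0,14
1h1v,other,0,0
1he1,other,32,29
1he8,other,0,0
1i2m,other,0,9
1i4d,other,0,0
1ib1,other,0,0
1ibr,other,0,0
1ira,other,0,0
1j2j,other,247,64
1jmo,other,0,1
1k5d,other,0,0
1k74,other,40,121
1kac,other,2,0
1klu,other,0,0
1ktz,other,0,0
1kxp,other,40,63
1ml0,other,0,41
1n2c,other,0,0
1qa9,other,0,0
1r8s,other,0,0
1rlb,other,3,0
1s1q,other,33,21
1sbb,other,0,0
1t6b,other,0,0
1wq1,other,15,8
1xd3,other,63,122
1xqs,other,0,1
1y64,other,0,0
1z0k,other,96,50
1z5y,other,28,0
1zhi,other,0,0
2ajf,other,0,0
2btf,other,0,11
2c0l,other,0,1
2cfh,other,123,94
2h7v,other,0,0
2hle,other,54,54
2hqs,other,26,0
2hrk,other,0,3
2nz8,other,37,29
2oob,other,3,39
2ot3,other,2,7
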