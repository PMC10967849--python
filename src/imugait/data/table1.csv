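trial,SD,LW,US,DS,USL,DSL,TL,TR,LS,RS
1,12000,19850,23768,23819,11685,11625,23584,22926,13835,12244
2,12000,19760,23818,23862,11323,11347,23691,23768,12847,13745
3,11998,19863,23633,23784,11569,11572,23396,23294,14354,12961
4,11999,19968,23897,23990,11353,11190,23281,22543,14242,14485
5,12000,19852,23778,23778,11992,11670,23030,23849,13372,13656
6,11994,19931,23895,23692,11509,11309,23577,22741,14561,13304
7,12000,19931,23951,23586,11776,11740,23888,23645,13112,14472
8,12002,19803,23743,23541,11456,11466,23132,23560,12997,14447
9,12000,19984,23953,23900,11187,11270,23503,23865,12783,12652
10,11986,19818,23845,23596,11178,11859,23701,22740,14815,14413
11,12000,19872,23788,23898,11912,11620,23942,23899,12435,12133
12,11985,19900,23934,23733,11238,11552,23852,23308,14132,14659
13,12000,19914,23869,23671,11123,11392,22737,22588,12579,13929
14,11995,19940,23793,23835,11607,11929,23176,22976,13502,12503
15,11998,19807,23811,23889,11255,11973,23062,23569,14577,14488
16,12000,19863,23591,23760,11928,11356,23924,22872,13954,14751
17,12000,19945,23851,23579,11689,11244,23040,23845,12975,13747
18,11997,19948,23916,23851,11524,11278,23060,23926,12986,12885
19,12002,19894,23655,23951,11279,11721,23052,22989,13762,14419
20,12000,19937,23889,23916,11807,11199,22793,23953,14409,12288
21,11986,19889,23500,23553,11113,11823,23767,23397,13892,13534
22,12000,19975,23982,23678,11873,11216,23679,23269,13458,14566
23,11985,19889,23693,23799,11595,11769,22976,23759,14776,13311
24,12000,19971,24012,23701,11224,11435,22951,22834,14380,13768
25,11995,19869,23927,23980,11389,11834,23976,23456,14392,12697
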