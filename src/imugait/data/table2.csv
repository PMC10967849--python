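trial,LW,L-HS,R-TO,R-HMax,R-HS,L-TO,L-HMax
1,19850,2504,4817,2981,2202,4615,2731
2,19760,2129,4702,2769,2358,4876,2926
3,19863,2391,4676,2783,2091,4895,3027
4,19968,2213,4956,2796,2315,4983,2705
5,19852,2318,4484,2980,2250,4640,3180
6,19931,2242,4465,2791,2380,5054,2999
7,19931,2457,5060,2791,2271,4952,2400
8,19803,2220,4453,2874,2219,4951,3086
9,19984,2188,4599,2997,2166,4953,3081
10,19818,2367,4527,2776,2444,5059,2645
11,19872,2466,5084,2783,2208,4578,2753
12,19900,2044,4756,2787,2387,4898,3028
13,19914,2117,4798,3088,2258,4634,3019
14,19940,2440,4502,2892,2515,4657,2934
15,19807,2355,4572,2874,2202,4976,2828
16,19863,2048,4592,2782,2377,4873,3191
17,19945,2311,4644,2792,2113,4854,3231
18,19948,2199,5023,2793,2156,4603,3174
19,19894,2597,4627,2786,2299,4863,2722
20,19937,2290,4622,3091,2142,4664,3128
21,19889,2082,4790,2785,2367,4592,3273
22,19975,2459,5077,2696,2155,4618,2970
23,19889,2043,4439,2785,2211,4637,3774
24,19971,2280,5067,2896,2321,4586,2821
25,19869,2454,4508,2882,2383,4579,3063
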