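expert,pair_1,pair_2,pair_3,pair_4,pair_5,pair_6,pair_7,pair_8,pair_9
1,0.55,0.35,0.25,0.88,0.55,0.85,0.50,0.05,0.99
2,0.65,0.60,0.18,0.71,0.20,0.99,0.43,0.15,0.59
3,0.40,0.55,0.65,0.69,0.15,0.45,0.15,0.25,0.60
4,0.55,0.50,0.30,0.55,0.45,0.52,0.25,0.35,0.42
5,0.70,0.70,0.45,0.70,0.50,0.70,0.60,0.49,0.80
6,0.45,0.65,0.10,0.58,0.05,0.90,0.45,0.10,0.79
7,0.50,0.62,0.30,0.66,0.35,0.96,0.35,0.05,0.66
8,0.40,0.40,0.05,0.80,0.10,0.70,0.65,0.25,0.82
9,0.65,0.55,0.10,0.99,0.05,0.69,0.80,0.50,0.60
10,0.65,0.60,0.05,0.89,0.20,0.85,0.15,0.45,0.70
11,0.45,0.25,0.42,0.77,0.15,0.80,0.45,0.03,0.55
12,0.55,0.30,0.05,0.15,0.05,0.70,0.55,0.55,0.75
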