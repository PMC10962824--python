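alternative,assessment_I,assessment_II
1,0.4712,0.7109
2,0.5179,0.7959
3,0.3795,0.6338
4,0.5312,0.8104
5,0.5260,0.6288
6,0.3325,0.4073
7,0.5099,0.6382
8,0.3169,0.4590
9,0.4583,0.7841
10,0.3753,0.6468
11,0.4647,0.6341
12,0.4644,0.7443
13,0.5605,0.6102
14,0.4209,0.5159
15,0.4667,0.7617
16,0.3609,0.4660
17,0.3440,0.6912
18,0.5866,0.5973
19,0.2935,0.4473
20,0.5118,0.8179
healthy,1.0000,1.0000
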