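patient,assessment,reference,expert_1,expert_2,expert_3
1,I,II,II,III,II
2,I,III,III,III,III
3,I,II,II,II,II
4,I,III,III,III,III
5,I,III,III,III,III
6,I,II,II,II,II
7,I,III,III,III,IV
8,I,II,II,II,II
9,I,II,II,II,III
10,I,II,II,II,II
11,I,II,II,III,II
12,I,II,II,II,II
13,I,III,III,III,III
14,I,II,II,II,II
15,I,II,II,III,II
16,I,II,II,II,II
17,I,II,II,II,II
18,I,III,III,IV,III
19,I,II,III,III,III
20,I,III,III,III,III
1,II,IV,III,IV,IV
2,II,IV,IV,IV,IV
3,II,III,III,III,III
4,II,IV,IV,IV,IV
5,II,III,III,III,III
6,II,II,II,II,III
7,II,III,III,III,III
8,II,II,II,II,II
9,II,IV,IV,IV,IV
10,II,III,III,III,III
11,II,III,III,III,III
12,II,IV,IV,IV,IV
13,II,III,III,III,III
14,II,III,III,III,III
15,II,IV,IV,IV,IV
16,II,II,III,III,II
17,II,IV,III,IV,IV
18,II,III,III,III,III
19,II,II,III,III,III
20,II,IV,IV,IV,IV
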