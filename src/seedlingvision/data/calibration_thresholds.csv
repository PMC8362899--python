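group,f_max,f_avg,f_min
1,0.20,0.18,0.16
2,0.25,0.24,0.23
3,0.24,0.22,0.20
4,0.18,0.17,0.16
5,0.18,0.17,0.16
6,0.24,0.23,0.22
7,0.25,0.24,0.23
8,0.16,0.16,0.16
9,0.24,0.23,0.22
10,0.16,0.16,0.16
11,0.21,0.20,0.19
12,0.16,0.16,0.16
13,0.17,0.17,0.17
14,0.22,0.21,0.20
15,0.21,0.19,0.17
16,0.25,0.22,0.19
17,0.20,0.19,0.18
18,0.25,0.25,0.15
19,0.23,0.20,0.17
20,0.22,0.21,0.20
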