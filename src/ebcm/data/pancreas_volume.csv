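age_years,value
0.5,7
1,9
2,12
3,15
4,18
6,24
8,30
10,36
12,42
14,50
16,58
18,64
20,68
22,70
25,72
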