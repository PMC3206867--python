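age_years,value
0.5,7.9
1,10.3
2,12.7
3,14.6
4,16.7
6,21
8,26
10,32
12,40
14,51
16,61
18,67
20,71
22,73
25,75
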