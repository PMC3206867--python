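age_years,value
0.5,3615.43
1,3523.73
2,3058.7
3,2611.53
4,2282.44
6,1818.07
8,1533.39
10,1342.18
12,1220.18
14,1076.44
16,926.182
18,828.581
20,786.331
22,773.143
25,759.375
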