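age_years,value
0.5,7.3
1,9.5
2,12.1
3,14.1
4,16
6,20.2
8,25.8
10,33
12,42
14,50
16,54
18,57
20,58
22,59
25,60
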