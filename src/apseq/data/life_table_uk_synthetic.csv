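age,q_annual
0,0.004
1,0.0002
5,0.0001
10,0.0001
15,0.0002
20,0.0003
25,0.0004
30,0.0006
35,0.0008
40,0.0013
45,0.002
50,0.0032
55,0.005
60,0.008
65,0.013
70,0.021
75,0.036
80,0.065
85,0.12
90,0.2
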