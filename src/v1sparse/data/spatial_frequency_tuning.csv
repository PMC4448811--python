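frequency_cdeg,probability
0.375,0.000221
0.53033,0.001893
0.75,0.010979
1.06066,0.043084
1.5,0.114401
2.12132,0.205542
3,0.249875
4.24264,0.205542
6,0.114401
8.48528,0.043084
12,0.010979
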