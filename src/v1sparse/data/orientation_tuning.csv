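orientation_deg,probability
0.0,0.125000
15.0,0.104167
30.0,0.062500
45.0,0.041667
60.0,0.062500
75.0,0.104167
90.0,0.125000
105.0,0.104167
120.0,0.062500
135.0,0.041667
150.0,0.062500
165.0,0.104167
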