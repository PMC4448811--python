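phase_deg,probability
0.0,0.212500
45.0,0.037500
90.0,0.212500
135.0,0.037500
180.0,0.212500
225.0,0.037500
270.0,0.212500
315.0,0.037500
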