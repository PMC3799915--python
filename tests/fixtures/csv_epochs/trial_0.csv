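1.5,-2.25,0.0,3.125
0.5,0.75,-1.0,2.0
-0.125,4.5,2.5,-3.0
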