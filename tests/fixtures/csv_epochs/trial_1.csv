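0.25,1.0,-0.5,0.125
-2.0,3.5,1.75,0.0
5.0,-1.25,0.625,2.25
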