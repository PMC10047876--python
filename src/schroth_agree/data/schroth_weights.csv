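,3c,3cp,4c,4cp
3c,1.00,0.75,0.50,0.00
3cp,0.75,1.00,0.00,0.00
4c,0.50,0.00,1.00,0.75
4cp,0.00,0.00,0.75,1.00
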