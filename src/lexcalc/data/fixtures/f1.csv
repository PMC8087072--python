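cat,10
hat,5
can,2
bat,1
rat,4
cap,3
cot,2
at,6
cats,1
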