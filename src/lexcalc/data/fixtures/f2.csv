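sail,seɪl,8
mail,meɪl,5
male,meɪl,3
pail,peɪl,4
pale,peɪl,2
tale,teɪl,1
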