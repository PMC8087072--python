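b,a,ˈ
d,ɑ,
f,e,
ɡ,ɛ,
k,ɛː,
l,ə,
m,i,
n,œ,
ɲ,ø,
ŋ,o,
p,ɔ,
ʀ,u,
s,y,
ʃ,ɑ̃,
t,ɛ̃,
v,œ̃,
z,ɔ̃,
ʒ,,
j,,
w,,
ɥ,,
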