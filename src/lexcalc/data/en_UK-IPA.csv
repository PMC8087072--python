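b,ɪ,ˈ
d,iː,
dʒ,i,
ð,ɛ,
f,a,
ɡ,ɑː,
h,ɒ,
j,ɔː,
k,ʊ,
l,uː,
m,ʌ,
n,ə,
ŋ,əː,
p,ɪə,
r,ɛː,
s,ʊə,
ʃ,eɪ,
t,aʊ,
tʃ,ʌɪ,
θ,əʊ,
v,ɔɪ,
w,,
z,,
ʒ,,
ʍ,,
x,,
ʔ,,
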