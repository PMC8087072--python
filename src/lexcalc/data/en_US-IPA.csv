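b,ɪ,ˈ
d,i,
dʒ,ɛ,
ð,æ,
f,ɑ,
ɡ,ɔ,
h,ʊ,
j,u,
k,ə,
l,eɪ,
m,aɪ,
n,aʊ,
ŋ,oʊ,
p,ɔɪ,
r,,
s,,
ʃ,,
t,,
tʃ,,
θ,,
v,,
w,,
z,,
ʒ,,
ʍ,,
x,,
ʔ,,
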