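b,a,ˈ
ç,aː,
d,ɛ,
f,ɛː,
ɡ,eː,
h,ɪ,
j,iː,
k,ɔ,
l,oː,
m,œ,
n,øː,
ŋ,ʊ,
p,uː,
pf,ʏ,
r,yː,
s,ə,
ʃ,aɪ,
t,aʊ,
ts,ɔʏ,
v,uɪ,
x,ɐ,
z,l̩,
ʔ,m̩,
tʃ,n̩,
dʒ,,
ʒ,,
i̯,,
u̯,,
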