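b,ɑ,ˈ
d,ɛ,
f,ɪ,
ɣ,ɔ,
h,ʏ,
j,ə,
k,aː,
l,eː,
m,i,
n,oː,
ŋ,y,
p,øː,
r,u,
s,ɛi,
t,œy,
v,ɑu,
ʋ,ɑi,
x,ɔi,
z,iu,
ɡ,yu,
c,ui,
ɲ,aːi,
ʃ,eːu,
ʒ,oːi,
,iː,
,yː,
,uː,
,ɔː,
,ɛː,
,œː,
,ɑː,
,ɑ̃,
,ɛ̃,
,ɔ̃,
,œ̃,
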