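b,a,ˈ
β,u,
d,e,
ð,i,
f,o,
ɡ,,
ɣ,,
ʝ,,
k,,
l,,
ʎ,,
m,,
n,,
ɲ,,
ŋ,,
p,,
r,,
ɾ,,
s,,
θ,,
t,,
tʃ,,
v,,
x,,
z,,
ʃ,,
j,,
w,,
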