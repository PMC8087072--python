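b,a,""""
B,u,
d,e,
D,i,
f,o,
g,,
G,,
jj,,
k,,
l,,
L,,
m,,
n,,
J,,
N,,
p,,
rr,,
r,,
s,,
T,,
t,,
tS,,
v,,
x,,
z,,
S,,
j,,
w,,
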