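b,I,""""
d,i,
dZ,E,
D,a,
f,A,
g,O,
h,U,
j,u,
k,V,
l,@,
m,e,
n,aI,
N,aU,
p,o,
r,OI,
s,3`,
S,@`,
t,,
tS,,
T,,
v,,
w,,
z,,
Z,,
W,,
x,,
?,,
4,,
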