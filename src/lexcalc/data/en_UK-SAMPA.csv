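b,I,""""
d,i:,
dZ,i,
D,E,
f,a,
g,A:,
h,Q,
j,O:,
k,U,
l,u:,
m,V,
n,@,
N,@:,
p,I@,
r,E:,
s,U@,
S,eI,
t,aU,
tS,VI,
T,@U,
v,OI,
w,,
z,,
Z,,
W,,
x,,
?,,
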