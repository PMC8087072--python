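b,I,'
d,i,
J,E,
D,@,
f,a,
g,c,
h,U,
y,u,
k,^,
l,x,
m,|,
n,e,
G,Y,
p,W,
r,o,
s,O,
S,R,
t,X,
C,N,
T,M,
v,L,
w,,
z,,
Z,,
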