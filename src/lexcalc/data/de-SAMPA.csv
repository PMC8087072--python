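b,a,""""
C,a:,
d,E,
f,E:,
g,e:,
h,I,
j,i:,
k,O,
l,o:,
m,9,
n,2:,
N,U,
p,u:,
pf,Y,
R,y:,
s,@,
S,aI,
t,aU,
ts,OY,
v,uI,
x,6,
z,,
?,,
tS,,
dZ,,
Z,,
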