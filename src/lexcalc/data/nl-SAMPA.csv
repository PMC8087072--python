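b,A,""""
d,E,
f,I,
G,O,
h,Y,
j,@,
k,a:,
l,e:,
m,i,
n,o:,
N,y,
p,2:,
r,u,
s,Ei,
t,9y,
v,Au,
P,Ai,
x,Oi,
z,iu,
g,yu,
c,ui,
J,a:i,
S,e:u,
Z,o:i,
,i:,
,y:,
,u:,
,O:,
,E:,
,9:,
,A:,
,A~,
,E~:,
,O~,
,9~,
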