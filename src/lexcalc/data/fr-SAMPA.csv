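b,a,""""
d,A,
f,e,
g,E,
k,E:,
l,@,
m,i,
n,9,
J,2,
N,o,
p,O,
R,u,
s,y,
S,a~,
t,e~,
v,9~,
z,o~,
Z,,
j,,
w,,
H,,
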