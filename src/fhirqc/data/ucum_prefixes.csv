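symbol,exponent
Y,24
Z,21
E,18
P,15
T,12
G,9
M,6
k,3
h,2
da,1
d,-1
c,-2
m,-3
u,-6
n,-9
p,-12
f,-15
a,-18
z,-21
y,-24
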