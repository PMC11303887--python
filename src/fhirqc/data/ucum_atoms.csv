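symbol,kind,metric,value,unit,dimension
m,base,1,1,,length
s,base,1,1,,time
g,base,1,1,,mass
rad,base,1,1,,angle
K,base,1,1,,temperature
C,base,1,1,,charge
cd,base,1,1,,luminosity
mol,base,1,1,,amount
10*,derived,0,10,1,
10^,derived,0,10,1,
%,derived,0,1/100,1,
sr,derived,1,1,rad2,
Hz,derived,1,1,/s,
N,derived,1,1,kg.m/s2,
Pa,derived,1,1,N/m2,
J,derived,1,1,N.m,
W,derived,1,1,J/s,
A,derived,1,1,C/s,
V,derived,1,1,J/C,
Ohm,derived,1,1,V/A,
S,derived,1,1,Ohm-1,
F,derived,1,1,C/V,
Gy,derived,1,1,J/kg,
Sv,derived,1,1,J/kg,
Bq,derived,1,1,/s,
lm,derived,1,1,cd.sr,
lx,derived,1,1,lm/m2,
L,derived,1,1,dm3,
l,derived,1,1,L,
min,derived,0,60,s,
h,derived,0,60,min,
d,derived,0,24,h,
wk,derived,0,7,d,
a,derived,0,1461/4,d,
mo,derived,0,487/16,d,
t,derived,1,1000,kg,
bar,derived,1,100000,Pa,
atm,derived,0,101325,Pa,
m[Hg],derived,1,133322,Pa,
m[H2O],derived,1,980665/100,Pa,
kat,derived,1,1,mol/s,
U,derived,1,1,umol/min,
eq,derived,1,1,mol,
osm,derived,1,1,mol,
g%,derived,1,1,g/dL,
cal,derived,1,4184/1000,J,
[in_i],derived,0,254/100,cm,
[ft_i],derived,0,12,[in_i],
[lb_av],derived,0,45359237/100000,g,
[oz_av],derived,0,1/16,[lb_av],
[IU],arbitrary,1,1,,
[iU],derived,1,1,[IU],
[arb],arbitrary,1,1,,
[CFU],arbitrary,0,1,,
Cel,special,1,1,K,
[degF],special,0,5/9,K,
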