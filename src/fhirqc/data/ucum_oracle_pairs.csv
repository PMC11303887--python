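unit_a,unit_b
mg/dL,g/L
ug/dL,mg/L
ng/mL,ug/L
g/dL,g/L
mg/L,ug/mL
pg/mL,ng/L
kg/m3,g/L
g%,g/dL
mm[Hg],kPa
cm[H2O],Pa
bar,kPa
atm,Pa
Pa,N/m2
mbar,hPa
min,s
h,min
d,s
wk,d
a,d
mo,h
ms,us
Hz,/s
/min,/s
kHz,10*3/s
J,N.m
cal,mJ
W.h,J
N,kg.m/s2
kN,N
mmol/L,umol/mL
mol/L,mmol/mL
nmol/L,pmol/mL
mosm/kg,mmol/kg
meq/L,mmol/L
kat,mol/s
U,umol/min
U/L,ukat/L
10*3/uL,10*9/L
10*6/uL,10*12/L
10*9/L,/nL
%,10*-2
mmol/mol,%
cm,m
mm,um
[in_i],cm
[ft_i],[in_i]
t,kg
[lb_av],g
[oz_av],[lb_av]
mL,cm3
uL,mm3
dL,cm3
m3,L
km/h,m/s
mg/(L.h),ug/(mL.min)
Gy,J/kg
mSv,uGy
V,J/C
[IU]/mL,[IU]/L
{RBC}/uL,/uL
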