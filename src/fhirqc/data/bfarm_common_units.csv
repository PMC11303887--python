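unit
%
/min
/uL
10*12/L
10*3/uL
10*6/uL
10*9/L
Cel
U/L
U/mL
[IU]/L
[IU]/mL
cm
d
fL
fmol/L
g
g/L
g/dL
h
kPa
kg
kg/m2
L
m
mL
mL/min
mg
mg/L
mg/dL
min
mm
mm[Hg]
mmol/L
mmol/mol
mol/L
mosm/kg
ng/L
ng/mL
nmol/L
pg
pg/mL
pmol/L
s
ug
ug/L
ug/dL
umol/L
wk
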