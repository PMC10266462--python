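guest,X,ddG_water_kJmol,sigma_water,ddG_chloroform_kJmol,sigma_chloroform
5,H,-13,1,-6,1
6,Me,-18,1,-7,0
7,NMe2,-26,1,-8,0
8,CF3,-24,1,-12,1
9,NO2,-31,1,-16,1
10,OMe,-23,1,-9,1
11,CHO,-24,1,-12,1
12,COMe,-30,1,-12,1
13,iPr,-22,1,-5,1
14,Et,-21,1,-6,2
15,F,-19,1,-11,0
16,Cl,-23,1,-12,1
17,Br,-24,1,-11,1
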