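#coding=physical
run_id,Buffer conc [mM],pH,SDS conc [mM],CyD conc [mM],BuOH conc [% v/v],V [kV],T [degC]
1,15,9.20,62.5,30,1.00,30,25
2,35,8.20,62.5,20,2.00,25,25
3,35,10.20,50.0,20,1.00,30,22
4,25,10.20,75.0,10,1.00,25,25
5,35,9.20,75.0,30,0.00,25,22
6,25,10.20,62.5,30,2.00,20,22
7,25,9.20,75.0,20,2.00,30,19
8,25,9.20,62.5,20,1.00,25,22
9,35,9.20,62.5,10,1.00,20,19
10,15,10.20,62.5,20,0.00,25,19
11,15,8.20,75.0,20,1.00,20,22
12,25,8.20,50.0,30,1.00,25,19
13,15,9.20,50.0,10,2.00,25,22
14,25,8.20,62.5,10,0.00,30,22
15,25,9.20,50.0,20,0.00,20,25
16,25,9.20,62.5,20,1.00,25,22
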