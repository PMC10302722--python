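#coding=physical
run_id,pH,Buffer conc [mM],CyD conc [mM],V [kV],BuOH conc [% v/v]
1,9.20,22,13.0,22,1.48
2,9.80,22,13.0,22,0.52
3,9.20,28,13.0,22,0.52
4,9.80,28,13.0,22,1.48
5,9.20,22,22.0,22,0.52
6,9.80,22,22.0,22,1.48
7,9.20,28,22.0,22,1.48
8,9.80,28,22.0,22,0.52
9,9.20,22,13.0,28,0.52
10,9.80,22,13.0,28,1.48
11,9.20,28,13.0,28,1.48
12,9.80,28,13.0,28,0.52
13,9.20,22,22.0,28,1.48
14,9.80,22,22.0,28,0.52
15,9.20,28,22.0,28,0.52
16,9.80,28,22.0,28,1.48
17,9.00,25,17.5,25,1.00
18,10.00,25,17.5,25,1.00
19,9.50,20,17.5,25,1.00
20,9.50,30,17.5,25,1.00
21,9.50,25,10.0,25,1.00
22,9.50,25,25.0,25,1.00
23,9.50,25,17.5,20,1.00
24,9.50,25,17.5,30,1.00
25,9.50,25,17.5,25,0.20
26,9.50,25,17.5,25,1.80
27,9.50,25,17.5,25,1.00
28,9.50,25,17.5,25,1.00
29,9.50,25,17.5,25,1.00
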