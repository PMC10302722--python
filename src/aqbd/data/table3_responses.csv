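run_id,R2,R3,R5,N_I2,t
1,6.35,-3.43,2.47,8400,9.23
2,3.70,1.45,3.05,18908,10.17
3,5.82,-2.60,3.37,7954,10.41
4,2.60,2.43,4.08,8604,11.89
5,4.47,-0.86,3.31,6884,8.68
6,1.81,3.32,4.74,12511,9.54
7,5.38,0.00,5.20,n.d.,9.79
8,1.63,3.11,4.79,8061,9.84
9,4.10,-1.77,2.94,4379,6.43
10,2.226,1.73,3.67,9325,6.86
11,4.09,-1.03,4.00,5713,7.35
12,2.54,1.37,3.06,8342,7.26
13,4.34,0.00,4.46,n.d.,6.17
14,1.59,2.34,3.80,9707,5.80
15,4.48,0.00,3.41,n.d.,6.32
16,1.42,3.13,4.92,13364,6.66
17,4.40,-1.66,3.61,5076,7.79
18,1.51,2.73,4.53,6878,8.25
19,3.71,1.15,2.26,25460,7.41
20,2.97,1.59,3.90,10100,8.66
21,5.31,-0.95,4.31,17255,9.29
22,2.26,2.29,3.96,12609,7.41
23,4.51,1.33,3.20,26097,11.39
24,2.92,1.27,3.77,19239,5.62
25,4.02,0.89,2.36,26779,7.47
26,2.87,1.63,3.91,10783,8.37
27,3.35,1.32,3.06,17716,7.91
28,3.56,1.36,2.98,18518,8.27
29,3.85,1.27,3.06,23917,8.04
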