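run_id,R2,R3,R5,N_I2,t
1,1.67,-0.88,2.64,13279,4.38
2,14.38,11.06,3.78,36880,10.65
3,1.00,-2.25,4.87,29692,5.22
4,2.53,-1.67,3.78,7550,9.51
5,3.83,-1.48,4.82,18090,8.04
6,0.87,-3.64,4.09,14510,10.56
7,4.58,0.00,4.32,19078,6.81
8,5.65,1.38,4.78,12229,8.35
9,5.81,2.74,7.14,3195,20.68
10,1.30,-2.50,3.23,6706,6.99
11,15.37,14.58,3.16,27893,13.32
12,5.94,3.16,2.74,14257,7.11
13,16.04,15.22,2.93,27987,10.38
14,18.87,19.85,2.80,36535,8.61
15,2.83,0.00,2.99,3809,8.91
16,5.34,1.10,4.64,12342,8.10
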