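[meta]
name exc_acid
resname EAC
head C1
tail C2
head_cap HH
tail_cap HT

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
C1 C 0.000000 0.350000 0.276000 12.011000
C2 C 0.000000 0.350000 0.276000 12.011000
C3 C 0.000000 0.350000 0.276000 12.011000
C4 C 0.520000 0.350000 0.276000 12.011000
O1 O -0.440000 0.296000 0.878000 15.999000
O2 O -0.530000 0.312000 0.711000 15.999000
H1 H 0.450000 0.120000 0.065000 1.008000
HH H 0.000000 0.242000 0.126000 1.008000
HT H 0.000000 0.242000 0.126000 1.008000

[bonds]
0 1 0.150000 30000.000
0 2 0.148661 30000.000
1 3 0.140000 30000.000
3 4 0.128062 30000.000
3 5 0.138924 30000.000
5 6 0.100000 30000.000
0 7 0.111803 30000.000
1 8 0.115758 30000.000

[angles]
1 0 2 90.0000 300.000
1 0 7 153.4349 300.000
2 0 7 115.2885 300.000
0 1 3 90.0000 300.000
0 1 8 149.7537 300.000
3 1 8 115.5904 300.000
1 3 4 128.6598 300.000
1 3 5 120.2564 300.000
4 3 5 111.0838 300.000
3 5 6 120.2564 300.000

[dihedrals]

[pairs14]
0 4
0 5
1 6
2 8
2 3
3 7
4 8
4 6
5 8
7 8

[coords]
0.000000000 0.000000000 0.000000000
0.150000000 0.000000000 0.000000000
0.000000000 0.140000000 -0.050000000
0.150000000 -0.140000000 0.000000000
0.050000000 -0.220000000 0.000000000
0.270000000 -0.210000000 0.000000000
0.270000000 -0.310000000 0.000000000
-0.100000000 -0.040000000 0.030000000
0.250000000 0.050000000 0.030000000
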