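[meta]
name exc_aromatic
resname EAR
head C1
tail C2
head_cap HH
tail_cap HT

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
C1 C 0.000000 0.350000 0.276000 12.011000
C2 C 0.280000 0.350000 0.276000 12.011000
O2 O -0.330000 0.300000 0.711000 15.999000
C3 C 0.450000 0.350000 0.276000 12.011000
O1 O -0.400000 0.296000 0.878000 15.999000
CA1 C 0.000000 0.355000 0.293000 12.011000
CA2 C 0.000000 0.355000 0.293000 12.011000
CA3 C 0.000000 0.355000 0.293000 12.011000
CA4 C 0.000000 0.355000 0.293000 12.011000
CA5 C 0.000000 0.355000 0.293000 12.011000
CA6 C 0.000000 0.355000 0.293000 12.011000
C10 C 0.520000 0.350000 0.276000 12.011000
O3 O -0.440000 0.296000 0.878000 15.999000
O4 O -0.530000 0.312000 0.711000 15.999000
H2 H 0.450000 0.120000 0.065000 1.008000
HH H 0.000000 0.242000 0.126000 1.008000
HT H 0.000000 0.242000 0.126000 1.008000

[bonds]
0 1 0.150000 30000.000
1 2 0.130000 30000.000
2 3 0.128062 30000.000
3 4 0.126491 30000.000
3 5 0.100000 30000.000
5 6 0.140000 30000.000
6 7 0.140000 30000.000
7 8 0.140000 30000.000
8 9 0.140000 30000.000
9 10 0.140000 30000.000
10 5 0.140000 30000.000
8 11 0.140000 30000.000
11 12 0.130384 30000.000
11 13 0.125300 30000.000
13 14 0.100000 30000.000
0 15 0.111803 30000.000
1 16 0.115758 30000.000

[angles]
1 0 15 153.4349 300.000
0 1 2 90.0000 300.000
0 1 16 149.7537 300.000
2 1 16 115.5904 300.000
1 2 3 128.6598 300.000
2 3 4 122.9052 300.000
2 3 5 128.6598 300.000
4 3 5 108.4349 300.000
3 5 6 120.0000 300.000
3 5 10 120.0000 300.000
6 5 10 120.0000 300.000
5 6 7 120.0000 300.000
6 7 8 120.0000 300.000
7 8 9 120.0000 300.000
7 8 11 120.0000 300.000
9 8 11 120.0000 300.000
8 9 10 120.0000 300.000
5 10 9 120.0000 300.000
8 11 12 122.4712 300.000
8 11 13 118.6105 300.000
12 11 13 118.9183 300.000
11 13 14 118.6105 300.000

[dihedrals]

[pairs14]
0 3
1 4
1 5
2 15
2 10
2 6
3 16
3 9
3 7
4 10
4 6
5 8
6 9
6 11
7 10
7 12
7 13
8 14
9 12
9 13
10 11
12 14
15 16

[coords]
0.000000000 0.000000000 0.000000000
0.150000000 0.000000000 0.000000000
0.150000000 -0.130000000 0.000000000
0.250000000 -0.210000000 0.000000000
0.370000000 -0.170000000 0.000000000
0.250000000 -0.310000000 0.000000000
0.128756443 -0.380000000 0.000000000
0.128756443 -0.520000000 0.000000000
0.250000000 -0.590000000 0.000000000
0.371243557 -0.520000000 0.000000000
0.371243557 -0.380000000 0.000000000
0.250000000 -0.730000000 0.000000000
0.140000000 -0.800000000 0.000000000
0.360000000 -0.790000000 0.000000000
0.360000000 -0.890000000 0.000000000
-0.100000000 -0.040000000 0.030000000
0.250000000 0.050000000 0.030000000
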