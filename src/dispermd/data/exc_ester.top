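[meta]
name exc_ester
resname EPE
head C1
tail C2
head_cap HH
tail_cap HT

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
C1 C 0.150000 0.350000 0.276000 12.011000
C2 C 0.000000 0.350000 0.276000 12.011000
O3 O -0.580000 0.312000 0.711000 15.999000
H1 H 0.430000 0.120000 0.065000 1.008000
C3 C 0.450000 0.350000 0.276000 12.011000
O1 O -0.400000 0.296000 0.878000 15.999000
O2 O -0.330000 0.300000 0.711000 15.999000
C4 C 0.280000 0.350000 0.276000 12.011000
HH H 0.000000 0.242000 0.126000 1.008000
HT H 0.000000 0.242000 0.126000 1.008000

[bonds]
0 1 0.150000 30000.000
0 2 0.139284 30000.000
2 3 0.100000 30000.000
1 4 0.140000 30000.000
4 5 0.122066 30000.000
4 6 0.134164 30000.000
6 7 0.140000 30000.000
0 8 0.111803 30000.000
1 9 0.123288 30000.000

[angles]
1 0 2 90.0000 300.000
1 0 8 153.4349 300.000
2 0 8 115.4833 300.000
0 1 4 90.0000 300.000
0 1 9 144.2042 300.000
4 1 9 108.9318 300.000
0 2 3 124.0563 300.000
1 4 5 124.9920 300.000
1 4 6 116.5651 300.000
5 4 6 118.4429 300.000
4 6 7 116.5651 300.000

[dihedrals]

[pairs14]
0 5
0 6
1 3
1 7
2 9
2 4
3 8
4 8
5 9
5 7
6 9
8 9

[coords]
0.000000000 0.000000000 0.000000000
0.150000000 0.000000000 0.000000000
0.000000000 0.130000000 0.050000000
0.080000000 0.190000000 0.050000000
0.150000000 -0.140000000 0.000000000
0.050000000 -0.210000000 0.000000000
0.270000000 -0.200000000 0.000000000
0.270000000 -0.340000000 0.000000000
-0.100000000 -0.040000000 -0.030000000
0.250000000 0.040000000 0.060000000
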