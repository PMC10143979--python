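[meta]
name api_small_neutral
resname SMN

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
C3 C 0.000000 0.350000 0.276000 12.011000
C4 C 0.000000 0.350000 0.276000 12.011000
C1 C 0.450000 0.350000 0.276000 12.011000
O1 O -0.400000 0.296000 0.878000 15.999000
O2 O -0.330000 0.300000 0.711000 15.999000
C2 C 0.280000 0.350000 0.276000 12.011000
C5 C 0.450000 0.350000 0.276000 12.011000
O3 O -0.400000 0.296000 0.878000 15.999000
O4 O -0.330000 0.300000 0.711000 15.999000
C6 C 0.280000 0.350000 0.276000 12.011000

[bonds]
0 1 0.140000 30000.000
0 2 0.150000 30000.000
2 3 0.124499 30000.000
2 4 0.143178 30000.000
4 5 0.144222 30000.000
1 6 0.150000 30000.000
6 7 0.124499 30000.000
6 8 0.143178 30000.000
8 9 0.144222 30000.000

[angles]
1 0 2 126.8699 300.000
0 1 6 126.8699 300.000
0 2 3 117.7664 300.000
0 2 4 125.9219 300.000
3 2 4 116.3072 300.000
2 4 5 122.8463 300.000
1 6 7 117.7664 300.000
1 6 8 125.9219 300.000
7 6 8 116.3072 300.000
6 8 9 122.8463 300.000

[dihedrals]

[pairs14]
0 8
0 7
0 5
1 3
1 4
1 9
2 6
3 5
7 9

[coords]
0.000000000 0.000000000 0.000000000
0.140000000 0.000000000 0.000000000
-0.090000000 0.120000000 0.000000000
-0.040000000 0.230000000 0.030000000
-0.230000000 0.120000000 -0.030000000
-0.310000000 0.240000000 -0.030000000
0.230000000 -0.120000000 0.000000000
0.180000000 -0.230000000 -0.030000000
0.370000000 -0.120000000 0.030000000
0.450000000 -0.240000000 0.030000000
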