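[meta]
name api_neutral_aromatic
resname ARO

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
CA1 C 0.000000 0.355000 0.293000 12.011000
CA2 C 0.000000 0.355000 0.293000 12.011000
CA3 C 0.000000 0.355000 0.293000 12.011000
CA4 C 0.000000 0.355000 0.293000 12.011000
CA5 C 0.000000 0.355000 0.293000 12.011000
CA6 C 0.000000 0.355000 0.293000 12.011000
O5 O -0.285000 0.300000 0.711000 15.999000
C7 C 0.285000 0.350000 0.276000 12.011000
C8 C 0.520000 0.350000 0.276000 12.011000
O6 O -0.440000 0.296000 0.878000 15.999000
O7 O -0.530000 0.312000 0.711000 15.999000
H8 H 0.450000 0.120000 0.065000 1.008000

[bonds]
0 1 0.140000 30000.000
1 2 0.140000 30000.000
2 3 0.140000 30000.000
3 4 0.140000 30000.000
4 5 0.140000 30000.000
5 0 0.140000 30000.000
0 6 0.131529 30000.000
6 7 0.138924 30000.000
3 8 0.140000 30000.000
8 9 0.125399 30000.000
8 10 0.136015 30000.000
10 11 0.100499 30000.000

[angles]
1 0 5 120.0000 300.000
1 0 6 119.6161 300.000
5 0 6 119.6161 300.000
0 1 2 120.0000 300.000
1 2 3 120.0000 300.000
2 3 4 120.0000 300.000
2 3 8 120.0000 300.000
4 3 8 120.0000 300.000
3 4 5 120.0000 300.000
0 5 4 120.0000 300.000
0 6 7 119.8686 300.000
3 8 9 113.4986 300.000
3 8 10 126.0274 300.000
9 8 10 120.4741 300.000
8 10 11 120.3168 300.000

[dihedrals]

[pairs14]
0 3
1 4
1 7
1 8
2 5
2 6
2 9
2 10
3 11
4 9
4 10
4 6
5 7
5 8
9 11

[coords]
0.140000000 0.000000000 0.000000000
0.070000000 0.121243557 0.000000000
-0.070000000 0.121243557 0.000000000
-0.140000000 0.000000000 0.000000000
-0.070000000 -0.121243557 0.000000000
0.070000000 -0.121243557 0.000000000
0.270000000 0.000000000 0.020000000
0.340000000 0.120000000 0.020000000
-0.280000000 0.000000000 0.000000000
-0.330000000 0.115000000 0.000000000
-0.360000000 -0.110000000 0.000000000
-0.460000000 -0.100000000 0.000000000
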