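[meta]
name api_donor_rich
resname DNR

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
C0 C 0.000000 0.350000 0.276000 12.011000
C1 C 0.150000 0.350000 0.276000 12.011000
C2 C 0.150000 0.350000 0.276000 12.011000
C3 C 0.150000 0.350000 0.276000 12.011000
O1 O -0.580000 0.312000 0.711000 15.999000
H1 H 0.430000 0.120000 0.065000 1.008000
O2 O -0.580000 0.312000 0.711000 15.999000
H2 H 0.430000 0.120000 0.065000 1.008000
O3 O -0.580000 0.312000 0.711000 15.999000
H3 H 0.430000 0.120000 0.065000 1.008000

[bonds]
0 1 0.158114 30000.000
1 2 0.160935 30000.000
2 3 0.160935 30000.000
1 4 0.143178 30000.000
4 5 0.098995 30000.000
2 6 0.152315 30000.000
6 7 0.102956 30000.000
3 8 0.143178 30000.000
8 9 0.107238 30000.000

[angles]
0 1 2 141.8112 300.000
0 1 4 108.0115 300.000
2 1 4 105.3509 300.000
1 2 3 137.5148 300.000
1 2 6 102.2474 300.000
3 2 6 102.2474 300.000
2 3 8 105.3509 300.000
1 4 5 115.4909 300.000
2 6 7 104.0234 300.000
3 8 9 113.4087 300.000

[dihedrals]

[pairs14]
0 3
0 6
0 5
1 8
1 7
2 5
2 9
3 4
3 7
4 6
6 8

[coords]
-0.150000000 -0.050000000 0.000000000
0.000000000 0.000000000 0.000000000
0.150000000 -0.050000000 0.030000000
0.300000000 0.000000000 0.000000000
0.000000000 0.140000000 0.030000000
0.080000000 0.190000000 0.000000000
0.150000000 -0.190000000 -0.030000000
0.240000000 -0.230000000 0.000000000
0.300000000 0.140000000 0.030000000
0.390000000 0.190000000 0.000000000
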