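[meta]
name api_ion_pair
resname IOP

[defaults]
fudge_lj 0.5
fudge_coul 0.5

[atoms]
C1 C 0.000000 0.350000 0.276000 12.011000
C2 C 0.000000 0.350000 0.276000 12.011000
C3 C 0.000000 0.350000 0.276000 12.011000
N1 N -0.900000 0.325000 0.711000 14.007000
H1 H 0.400000 0.120000 0.065000 1.008000
C4 C 0.900000 0.350000 0.276000 12.011000
O1 O -0.700000 0.296000 0.878000 15.999000
O2 O -0.700000 0.296000 0.878000 15.999000
NA Na 1.000000 0.333000 0.011600 22.990000

[bonds]
0 1 0.150000 30000.000
1 2 0.150000 30000.000
2 5 0.148661 30000.000
5 6 0.124097 30000.000
5 7 0.124499 30000.000
0 3 0.142127 30000.000
3 4 0.107703 30000.000

[angles]
1 0 3 129.2894 300.000
0 1 2 180.0000 300.000
1 2 5 137.7263 300.000
0 3 4 107.4880 300.000
2 5 6 126.2167 300.000
2 5 7 112.5578 300.000
6 5 7 121.1849 300.000

[dihedrals]

[pairs14]
0 5
1 4
1 6
1 7
2 3

[coords]
0.000000000 0.000000000 0.000000000
0.150000000 0.000000000 0.000000000
0.300000000 0.000000000 0.000000000
-0.090000000 0.110000000 0.000000000
-0.190000000 0.070000000 0.000000000
0.410000000 0.100000000 0.000000000
0.400000000 0.220000000 0.030000000
0.520000000 0.050000000 -0.030000000
0.680000000 0.160000000 0.000000000
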