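[meta]
label = pos1
lambda = 1.095
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, active pellet in applicator position 1; Lambda 1.095+-0.05

[radial]
# r_cm	g
0.5	1.012
1	1
1.5	0.996
2	0.997
2.5	0.991
3	0.984
3.5	0.977
4	0.971
5	0.96
6	0.943
7	0.926
8	0.907
9	0.886
10	0.865
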