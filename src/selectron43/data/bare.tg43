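[meta]
label = bare
lambda = 1.102
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, single pellet in water without applicator; Lambda 1.102+-0.06

[radial]
# r_cm	g
0.5	1.007
1	1
1.5	0.994
2	0.998
2.5	-
3	0.985
3.5	0.979
4	0.968
5	0.956
6	0.943
7	0.927
8	0.911
9	0.893
10	0.87
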