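[meta]
label = pos2
lambda = 1.095
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, active pellet in applicator position 2; Lambda not published for this position - pos1 value 1.095 reused (assumption)

[radial]
# r_cm	g
0.5	1.013
1	1
1.5	0.993
2	0.992
2.5	0.984
3	0.974
3.5	0.968
4	0.958
5	0.953
6	0.939
7	0.923
8	0.894
9	0.886
10	0.858
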