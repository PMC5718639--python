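[meta]
label = pos4
lambda = 1.095
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, active pellet in applicator position 4; Lambda not published for this position - pos1 value 1.095 reused (assumption)

[radial]
# r_cm	g
0.5	1.012
1	1
1.5	0.995
2	0.989
2.5	0.983
3	0.979
3.5	0.979
4	0.97
5	0.949
6	0.939
7	0.919
8	0.905
9	0.876
10	0.85
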