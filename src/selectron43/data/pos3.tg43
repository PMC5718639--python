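[meta]
label = pos3
lambda = 1.095
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, active pellet in applicator position 3; Lambda not published for this position - pos1 value 1.095 reused (assumption)

[radial]
# r_cm	g
0.5	1.013
1	1
1.5	0.995
2	0.989
2.5	0.983
3	0.979
3.5	0.98
4	0.971
5	0.948
6	0.943
7	0.924
8	0.909
9	0.873
10	0.842
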