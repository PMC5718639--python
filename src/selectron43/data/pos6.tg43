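[meta]
label = pos6
lambda = 1.095
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, active pellet in applicator position 6; Lambda not published for this position - pos1 value 1.095 reused (assumption)

[radial]
# r_cm	g
0.5	1.012
1	1
1.5	0.995
2	0.99
2.5	0.984
3	0.981
3.5	0.979
4	0.971
5	0.948
6	0.938
7	0.917
8	0.905
9	0.878
10	0.851
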