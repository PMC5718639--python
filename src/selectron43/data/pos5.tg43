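[meta]
label = pos5
lambda = 1.095
L_cm = 0.15
geometry_model = point
medium = water
provenance = Monte Carlo, active pellet in applicator position 5; Lambda not published for this position - pos1 value 1.095 reused (assumption)

[radial]
# r_cm	g
0.5	1.011
1	1
1.5	0.995
2	0.992
2.5	0.986
3	0.978
3.5	0.972
4	0.964
5	0.953
6	0.939
7	0.922
8	0.899
9	0.883
10	0.86
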