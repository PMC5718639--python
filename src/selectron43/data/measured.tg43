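[meta]
label = measured
lambda = 1.093
L_cm = 0.15
geometry_model = point
medium = plexiglas
provenance = TLD in Plexiglas, pellet in applicator position 1; Lambda 1.093+-0.08; anisotropy grid measured 15-165 deg; radial table reused from the pos1 Monte Carlo column (no measured g table published)

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

[anisotropy]
theta_deg\r_cm	1	2	3	5	7
15	-	0.892	0.903	0.921	0.92
30	-	-	0.956	0.961	0.979
45	0.973	0.998	1	0.996	0.997
60	0.989	-	0.999	0.992	0.995
75	-	0.997	1.003	1.005	-
90	1	1	1	1	1
105	-	1.002	1.01	1.007	1.01
120	-	-	1.003	1.006	1.003
135	0.894	0.936	0.948	0.988	0.993
150	-	-	0.944	0.953	0.958
165	-	0.899	0.902	0.939	0.938
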