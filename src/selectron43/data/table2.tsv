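# Measured anisotropy function F(r, theta) of the active pellet in position 1
# inside the applicator (TLD, Plexiglas phantom). Rows: theta (degrees from the
# applicator longitudinal axis); columns: r (cm). "-" = no printed value.
# The 75-degree row prints only three values; they are stored at r = 2, 3, 5 cm.
theta_deg	1	2	3	5	7
15	-	0.892	0.903	0.921	0.920
30	-	-	0.956	0.961	0.979
45	0.973	0.998	1	0.996	0.997
60	0.989	-	0.999	0.992	0.995
75	-	0.997	1.003	1.005	-
90	1	1	1	1	1
105	-	1.002	1.010	1.007	1.010
120	-	-	1.003	1.006	1.003
135	0.894	0.936	0.948	0.988	0.993
150	-	-	0.944	0.953	0.958
165	-	0.899	0.902	0.939	0.938
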