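# Radial dose function (point-source approximation), Monte Carlo in water.
# Columns: r (cm); bare pellet without applicator; single active pellet in
# positions 1-6 inside the applicator central tubing. "-" = no printed value.
r_cm	bare	pos1	pos2	pos3	pos4	pos5	pos6
0.5	1.007	1.012	1.013	1.013	1.012	1.011	1.012
1	1	1	1	1	1	1	1
1.5	0.994	0.996	0.993	0.995	0.995	0.995	0.995
2	0.998	0.997	0.992	0.989	0.989	0.992	0.990
2.5	-	0.991	0.984	0.983	0.983	0.986	0.984
3	0.985	0.984	0.974	0.979	0.979	0.978	0.981
3.5	0.979	0.977	0.968	0.980	0.979	0.972	0.979
4	0.968	0.971	0.958	0.971	0.970	0.964	0.971
5	0.956	0.960	0.953	0.948	0.949	0.953	0.948
6	0.943	0.943	0.939	0.943	0.939	0.939	0.938
7	0.927	0.926	0.923	0.924	0.919	0.922	0.917
8	0.911	0.907	0.894	0.909	0.905	0.899	0.905
9	0.893	0.886	0.886	0.873	0.876	0.883	0.878
10	0.870	0.865	0.858	0.842	0.850	0.860	0.851
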