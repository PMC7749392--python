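parameter,family,r_A,p_A,r_B,p_B
pmt,aggregation,-0.545,0.001,-0.515,0.001
bem,aggregation,0.594,0.001,0.524,0.001
peak30,aggregation,0.212,,0.222,
peak180,aggregation,-0.437,0.002,-0.393,0.007
ratio30_180,aggregation,0.540,0.001,0.484,0.001
y0,aggregation,0.059,,-0.040,
xc1,aggregation,-0.560,0.001,-0.525,0.001
a,aggregation,0.166,,0.143,
w,aggregation,-0.347,0.018,-0.292,0.049
k2,aggregation,0.139,,0.199,
xc2,aggregation,0.352,0.016,0.349,0.017
b,aggregation,-0.257,,-0.255,0.087
k3,aggregation,-0.218,,-0.146,
xc3,aggregation,-0.506,0.001,-0.509,0.001
e_rmax,extension,0.442,0.002,0.521,0.001
r_max,extension,0.150,,0.066,
a_rmax,extension,0.398,0.002,0.396,0.002
e_max,extension,0.516,0.001,0.614,0.001
a_max,extension,0.493,0.001,0.499,0.001
ratio_ermax_rmax,extension,0.235,,0.370,
hmw_gliadins,protein,0.026,,0.029,
mmw_gliadins,protein,0.433,0.003,0.390,0.007
lmw_gliadins,protein,0.370,0.011,0.374,0.010
gliadins,protein,0.327,0.026,0.301,0.042
hmw_glutenins,protein,-0.033,,0.061,
mmw_glutenins,protein,-0.507,0.001,-0.487,0.001
lmw_glutenins,protein,-0.309,0.037,-0.297,0.045
glutenins,protein,-0.327,0.026,-0.301,0.042
glia_glut_ratio,protein,0.327,0.026,0.301,0.042
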