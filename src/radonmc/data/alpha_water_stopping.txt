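# Linear stopping power of alpha particles in liquid water (unit density)
# provenance: effective-charge-scaled proton stopping + low-E power law, range-calibrated x1.04 (R(6 MeV)=48.2 um, R(7.69 MeV)=70.9 um)
# energy_MeV   S_keV_per_um
1.000000e-03  2.905102e+01
1.052801e-03  2.957894e+01
1.108390e-03  3.011645e+01
1.166915e-03  3.066374e+01
1.228529e-03  3.122096e+01
1.293397e-03  3.178832e+01
1.361690e-03  3.236598e+01
1.433589e-03  3.295414e+01
1.509284e-03  3.355299e+01
1.588976e-03  3.416272e+01
1.672876e-03  3.478353e+01
1.761206e-03  3.541562e+01
1.854199e-03  3.605920e+01
1.952103e-03  3.671448e+01
2.055177e-03  3.738166e+01
2.163692e-03  3.806097e+01
2.277938e-03  3.875262e+01
2.398216e-03  3.945684e+01
2.524845e-03  4.017385e+01
2.658159e-03  4.090390e+01
2.798513e-03  4.164721e+01
2.946278e-03  4.240404e+01
3.101845e-03  4.317461e+01
3.265626e-03  4.395919e+01
3.438055e-03  4.475802e+01
3.619589e-03  4.557137e+01
3.810707e-03  4.639950e+01
4.011917e-03  4.724268e+01
4.223751e-03  4.810119e+01
4.446770e-03  4.897529e+01
4.681565e-03  4.986528e+01
4.928757e-03  5.077144e+01
5.189002e-03  5.169407e+01
5.462987e-03  5.263346e+01
5.751439e-03  5.358993e+01
6.055122e-03  5.456377e+01
6.374840e-03  5.555532e+01
6.711439e-03  5.656488e+01
7.065811e-03  5.759278e+01
7.438894e-03  5.863937e+01
7.831677e-03  5.970498e+01
8.245199e-03  6.078995e+01
8.680555e-03  6.189463e+01
9.138899e-03  6.301939e+01
9.621443e-03  6.416459e+01
1.012947e-02  6.533061e+01
1.066431e-02  6.651781e+01
1.122740e-02  6.772658e+01
1.182022e-02  6.895732e+01
1.244435e-02  7.021042e+01
1.310142e-02  7.148630e+01
1.379319e-02  7.278536e+01
1.452149e-02  7.410803e+01
1.528824e-02  7.545474e+01
1.609548e-02  7.682592e+01
1.694534e-02  7.822201e+01
1.784007e-02  7.964348e+01
1.878205e-02  8.109077e+01
1.977377e-02  8.256437e+01
2.081784e-02  8.406474e+01
2.191705e-02  8.559238e+01
2.307430e-02  8.714778e+01
2.429265e-02  8.873145e+01
2.557533e-02  9.034389e+01
2.692574e-02  9.198564e+01
2.834745e-02  9.365722e+01
2.984423e-02  9.535918e+01
3.142004e-02  9.709206e+01
3.307905e-02  9.885644e+01
3.482567e-02  1.006529e+02
3.666450e-02  1.024820e+02
3.860043e-02  1.043443e+02
4.063858e-02  1.062404e+02
4.278435e-02  1.081711e+02
4.504341e-02  1.101368e+02
4.742176e-02  1.121382e+02
4.992568e-02  1.141760e+02
5.256182e-02  1.162508e+02
5.533715e-02  1.183633e+02
5.825901e-02  1.205143e+02
6.133516e-02  1.227043e+02
6.457373e-02  1.249341e+02
6.798330e-02  1.272044e+02
7.157290e-02  1.295160e+02
7.535203e-02  1.318696e+02
7.933071e-02  1.342659e+02
8.351947e-02  1.367058e+02
8.792939e-02  1.391901e+02
9.257217e-02  1.417195e+02
9.746009e-02  1.442948e+02
1.026061e-01  1.471553e+02
1.080238e-01  1.502558e+02
1.137276e-01  1.533403e+02
1.197326e-01  1.564055e+02
1.260546e-01  1.594479e+02
1.327104e-01  1.624644e+02
1.397177e-01  1.654517e+02
1.470950e-01  1.684063e+02
1.548617e-01  1.713135e+02
1.630386e-01  1.741397e+02
1.716473e-01  1.769091e+02
1.807104e-01  1.796532e+02
1.902522e-01  1.824055e+02
2.002977e-01  1.852018e+02
2.108737e-01  1.880889e+02
2.220080e-01  1.910618e+02
2.337303e-01  1.940821e+02
2.460716e-01  1.971088e+02
2.590645e-01  2.000984e+02
2.727434e-01  2.030048e+02
2.871445e-01  2.057796e+02
3.023061e-01  2.083744e+02
3.182682e-01  2.108635e+02
3.350732e-01  2.132786e+02
3.527654e-01  2.155812e+02
3.713919e-01  2.177313e+02
3.910018e-01  2.196876e+02
4.116472e-01  2.214186e+02
4.333826e-01  2.229669e+02
4.562658e-01  2.243823e+02
4.803571e-01  2.257121e+02
5.057206e-01  2.270060e+02
5.324232e-01  2.282984e+02
5.605358e-01  2.295225e+02
5.901328e-01  2.305865e+02
6.212925e-01  2.314429e+02
6.540975e-01  2.321791e+02
6.886346e-01  2.327924e+02
7.249953e-01  2.333247e+02
7.632759e-01  2.338093e+02
8.035778e-01  2.339854e+02
8.460077e-01  2.321109e+02
8.906779e-01  2.285169e+02
9.377067e-01  2.236511e+02
9.872188e-01  2.175606e+02
1.039345e+00  2.131918e+02
1.094224e+00  2.096232e+02
1.152000e+00  2.063410e+02
1.212827e+00  2.029333e+02
1.276866e+00  1.990505e+02
1.344286e+00  1.947920e+02
1.415266e+00  1.903136e+02
1.489993e+00  1.857207e+02
1.568667e+00  1.809895e+02
1.651494e+00  1.760781e+02
1.738695e+00  1.711695e+02
1.830500e+00  1.663097e+02
1.927153e+00  1.614699e+02
2.028909e+00  1.567989e+02
2.136038e+00  1.522952e+02
2.248823e+00  1.479287e+02
2.367564e+00  1.436959e+02
2.492574e+00  1.395933e+02
2.624185e+00  1.356205e+02
2.762745e+00  1.317720e+02
2.908621e+00  1.280362e+02
3.062200e+00  1.244032e+02
3.223888e+00  1.208728e+02
3.394113e+00  1.174423e+02
3.573326e+00  1.141220e+02
3.762002e+00  1.109583e+02
3.960640e+00  1.077577e+02
4.169766e+00  1.043343e+02
4.389935e+00  1.007912e+02
4.621729e+00  9.732016e+01
4.865762e+00  9.389847e+01
5.122680e+00  9.061924e+01
5.393163e+00  8.747845e+01
5.677929e+00  8.449097e+01
5.977730e+00  8.163531e+01
6.293362e+00  7.887037e+01
6.625659e+00  7.616283e+01
6.975501e+00  7.349829e+01
7.343816e+00  7.091402e+01
7.731578e+00  6.844795e+01
8.139815e+00  6.608161e+01
8.569607e+00  6.378201e+01
9.022092e+00  6.156874e+01
9.498469e+00  5.944678e+01
1.000000e+01  5.740800e+01
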