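# material: aluminum (X-ray tube filtration only)
# density_g_cm3: 2.699
# provenance: scripts/build_material_tables.py
energy_keV,pe_cm2g,compton_cm2g,rayleigh_cm2g,mu_en_cm2g
5.00,2.150919e+02,9.045760e-02,1.299604e+00,2.150927e+02
5.50,1.605271e+02,9.655728e-02,1.142696e+00,1.605282e+02
6.00,1.228960e+02,1.019218e-01,1.016053e+00,1.228971e+02
6.50,9.612092e+01,1.066628e-01,9.119845e-01,9.612224e+01
7.00,7.656159e+01,1.108724e-01,8.251599e-01,7.656306e+01
7.50,6.194751e+01,1.146269e-01,7.517748e-01,6.194914e+01
8.00,5.081310e+01,1.179892e-01,6.890473e-01,5.081488e+01
8.50,4.218381e+01,1.210120e-01,6.348994e-01,4.218575e+01
9.00,3.539463e+01,1.237389e-01,5.877506e-01,3.539673e+01
9.50,2.998130e+01,1.262069e-01,5.463785e-01,2.998355e+01
10.00,2.561309e+01,1.284472e-01,5.098243e-01,2.561550e+01
10.50,2.205011e+01,1.304861e-01,4.773258e-01,2.205268e+01
11.00,1.911553e+01,1.323464e-01,4.482707e-01,1.911825e+01
11.50,1.667706e+01,1.340474e-01,4.221613e-01,1.667994e+01
12.00,1.463442e+01,1.356060e-01,3.985895e-01,1.463745e+01
12.50,1.291065e+01,1.370367e-01,3.772176e-01,1.291383e+01
13.00,1.144606e+01,1.383522e-01,3.577643e-01,1.144939e+01
13.50,1.019383e+01,1.395634e-01,3.399929e-01,1.019731e+01
14.00,9.116935e+00,1.406803e-01,3.237037e-01,9.120571e+00
14.50,8.185819e+00,1.417114e-01,3.087263e-01,8.189605e+00
15.00,7.376694e+00,1.426642e-01,2.949153e-01,7.380629e+00
15.50,6.670273e+00,1.435455e-01,2.821452e-01,6.674356e+00
16.00,6.050811e+00,1.443614e-01,2.703078e-01,6.055041e+00
16.50,5.505366e+00,1.451172e-01,2.593087e-01,5.509742e+00
17.00,5.023238e+00,1.458176e-01,2.490660e-01,5.027759e+00
17.50,4.595525e+00,1.464671e-01,2.395075e-01,4.600191e+00
18.00,4.214784e+00,1.470695e-01,2.305699e-01,4.219594e+00
18.50,3.874759e+00,1.476284e-01,2.221972e-01,3.879711e+00
19.00,3.570166e+00,1.481469e-01,2.143400e-01,3.575259e+00
19.50,3.296520e+00,1.486279e-01,2.069540e-01,3.301754e+00
20.00,3.050000e+00,1.490741e-01,2.000000e-01,3.055374e+00
20.50,2.827337e+00,1.494879e-01,1.934429e-01,2.832850e+00
21.00,2.625722e+00,1.498713e-01,1.872511e-01,2.631373e+00
21.50,2.442732e+00,1.502266e-01,1.813964e-01,2.448520e+00
22.00,2.276273e+00,1.505554e-01,1.758530e-01,2.282197e+00
22.50,2.124524e+00,1.508596e-01,1.705981e-01,2.130583e+00
23.00,1.985900e+00,1.511406e-01,1.656105e-01,1.992094e+00
23.50,1.859018e+00,1.513998e-01,1.608714e-01,1.865344e+00
24.00,1.742663e+00,1.516386e-01,1.563635e-01,1.749122e+00
24.50,1.635769e+00,1.518583e-01,1.520710e-01,1.642359e+00
25.00,1.537397e+00,1.520599e-01,1.479795e-01,1.544118e+00
25.50,1.446717e+00,1.522445e-01,1.440759e-01,1.453567e+00
26.00,1.362993e+00,1.524131e-01,1.403481e-01,1.369972e+00
26.50,1.285574e+00,1.525665e-01,1.367850e-01,1.292681e+00
27.00,1.213878e+00,1.527057e-01,1.333765e-01,1.221112e+00
27.50,1.147389e+00,1.528313e-01,1.301132e-01,1.154748e+00
28.00,1.085642e+00,1.529442e-01,1.269864e-01,1.093127e+00
28.50,1.028225e+00,1.530450e-01,1.239881e-01,1.035834e+00
29.00,9.747653e-01,1.531344e-01,1.211109e-01,9.824977e-01
29.50,9.249289e-01,1.532129e-01,1.183480e-01,9.327838e-01
30.00,8.784149e-01,1.532812e-01,1.156929e-01,8.863915e-01
30.50,8.349518e-01,1.533396e-01,1.131399e-01,8.430493e-01
31.00,7.942944e-01,1.533888e-01,1.106833e-01,8.025119e-01
31.50,7.562206e-01,1.534293e-01,1.083182e-01,7.645572e-01
32.00,7.205290e-01,1.534613e-01,1.060396e-01,7.289839e-01
32.50,6.870368e-01,1.534854e-01,1.038432e-01,6.956092e-01
33.00,6.555776e-01,1.535019e-01,1.017248e-01,6.642667e-01
33.50,6.260001e-01,1.535112e-01,9.968045e-02,6.348050e-01
34.00,5.981659e-01,1.535136e-01,9.770661e-02,6.070859e-01
34.50,5.719490e-01,1.535096e-01,9.579982e-02,5.809833e-01
35.00,5.472339e-01,1.534992e-01,9.395689e-02,5.563817e-01
35.50,5.239151e-01,1.534830e-01,9.217480e-02,5.331755e-01
36.00,5.018954e-01,1.534610e-01,9.045074e-02,5.112678e-01
36.50,4.810861e-01,1.534337e-01,8.878204e-02,4.905696e-01
37.00,4.614054e-01,1.534012e-01,8.716621e-02,4.709992e-01
37.50,4.427779e-01,1.533638e-01,8.560089e-02,4.524814e-01
38.00,4.251344e-01,1.533216e-01,8.408386e-02,4.349467e-01
38.50,4.084111e-01,1.532750e-01,8.261302e-02,4.183314e-01
39.00,3.925487e-01,1.532240e-01,8.118640e-02,4.025765e-01
39.50,3.774929e-01,1.531690e-01,7.980212e-02,3.876273e-01
40.00,3.631932e-01,1.531100e-01,7.845841e-02,3.734335e-01
40.50,3.496029e-01,1.530473e-01,7.715360e-02,3.599483e-01
41.00,3.366786e-01,1.529810e-01,7.588611e-02,3.471284e-01
41.50,3.243801e-01,1.529112e-01,7.465443e-02,3.349337e-01
42.00,3.126703e-01,1.528382e-01,7.345713e-02,3.233268e-01
42.50,3.015143e-01,1.527620e-01,7.229286e-02,3.122731e-01
43.00,2.908799e-01,1.526828e-01,7.116035e-02,3.017404e-01
43.50,2.807372e-01,1.526007e-01,7.005836e-02,2.916985e-01
44.00,2.710580e-01,1.525158e-01,6.898575e-02,2.821196e-01
44.50,2.618163e-01,1.524283e-01,6.794140e-02,2.729774e-01
45.00,2.529878e-01,1.523383e-01,6.692426e-02,2.642477e-01
45.50,2.445496e-01,1.522458e-01,6.593334e-02,2.559078e-01
46.00,2.364805e-01,1.521510e-01,6.496769e-02,2.479362e-01
46.50,2.287607e-01,1.520540e-01,6.402639e-02,2.403133e-01
47.00,2.213714e-01,1.519549e-01,6.310858e-02,2.330202e-01
47.50,2.142952e-01,1.518537e-01,6.221343e-02,2.260396e-01
48.00,2.075159e-01,1.517505e-01,6.134015e-02,2.193552e-01
48.50,2.010179e-01,1.516455e-01,6.048799e-02,2.129515e-01
49.00,1.947870e-01,1.515387e-01,5.965623e-02,2.068143e-01
49.50,1.888096e-01,1.514302e-01,5.884417e-02,2.009298e-01
50.00,1.830729e-01,1.513200e-01,5.805117e-02,1.952856e-01
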