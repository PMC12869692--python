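# material: air
# density_g_cm3: 0.001205
# composition (mass fractions): C=0.000124, N=0.755267, O=0.231781, Ar=0.012827
# provenance: scripts/build_material_tables.py (elemental anchors + Klein-Nishina; reference-table agreement ~few %)
# columns: energy_keV, pe_cm2g, compton_cm2g, rayleigh_cm2g, mu_en_cm2g
energy_keV,pe_cm2g,compton_cm2g,rayleigh_cm2g,mu_en_cm2g
10.00,4.844007e+00,1.496584e-01,2.014951e-01,4.846815e+00
10.50,4.143954e+00,1.511847e-01,1.886509e-01,4.146927e+00
11.00,3.570930e+00,1.525612e-01,1.771676e-01,3.574066e+00
11.50,3.097585e+00,1.538055e-01,1.668485e-01,3.100883e+00
12.00,2.703308e+00,1.549323e-01,1.575324e-01,2.706768e+00
12.50,2.372375e+00,1.559545e-01,1.490857e-01,2.375996e+00
13.00,2.092653e+00,1.568831e-01,1.413972e-01,2.096434e+00
13.50,1.854680e+00,1.577276e-01,1.343736e-01,1.858619e+00
14.00,1.651007e+00,1.584963e-01,1.279357e-01,1.655104e+00
14.50,1.475717e+00,1.591965e-01,1.220162e-01,1.479970e+00
15.00,1.324070e+00,1.598345e-01,1.165578e-01,1.328478e+00
15.50,1.192241e+00,1.604161e-01,1.115107e-01,1.196804e+00
16.00,1.077121e+00,1.609463e-01,1.068323e-01,1.081837e+00
16.50,9.761642e-01,1.614293e-01,1.024852e-01,9.810323e-01
17.00,8.872747e-01,1.618692e-01,9.843701e-02,8.922940e-01
17.50,8.087163e-01,1.622696e-01,9.465925e-02,8.138857e-01
18.00,7.390423e-01,1.626336e-01,9.112689e-02,7.443608e-01
18.50,6.770415e-01,1.629640e-01,8.781781e-02,6.825079e-01
19.00,6.216941e-01,1.632634e-01,8.471242e-02,6.273076e-01
19.50,5.721384e-01,1.635342e-01,8.179330e-02,5.778978e-01
20.00,5.276420e-01,1.637785e-01,7.904492e-02,5.335463e-01
20.50,4.875808e-01,1.639981e-01,7.645339e-02,4.936289e-01
21.00,4.514199e-01,1.641948e-01,7.400625e-02,4.576109e-01
21.50,4.187000e-01,1.643701e-01,7.169230e-02,4.250327e-01
22.00,3.890244e-01,1.645257e-01,6.950144e-02,3.954980e-01
22.50,3.620502e-01,1.646627e-01,6.742455e-02,3.686636e-01
23.00,3.374794e-01,1.647824e-01,6.545335e-02,3.442314e-01
23.50,3.150522e-01,1.648860e-01,6.358034e-02,3.219420e-01
24.00,2.945418e-01,1.649743e-01,6.179869e-02,3.015684e-01
24.50,2.757494e-01,1.650485e-01,6.010218e-02,2.829119e-01
25.00,2.585004e-01,1.651094e-01,5.848513e-02,2.657977e-01
25.50,2.426407e-01,1.651578e-01,5.694232e-02,2.500719e-01
26.00,2.280345e-01,1.651944e-01,5.546901e-02,2.355985e-01
26.50,2.145612e-01,1.652199e-01,5.406080e-02,2.222573e-01
27.00,2.021142e-01,1.652351e-01,5.271368e-02,2.099412e-01
27.50,1.905983e-01,1.652405e-01,5.142393e-02,1.985554e-01
28.00,1.799287e-01,1.652366e-01,5.018814e-02,1.880150e-01
28.50,1.700298e-01,1.652240e-01,4.900314e-02,1.782443e-01
29.00,1.608339e-01,1.652032e-01,4.786600e-02,1.691756e-01
29.50,1.522800e-01,1.651746e-01,4.677402e-02,1.607482e-01
30.00,1.443137e-01,1.651387e-01,4.572469e-02,1.529074e-01
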