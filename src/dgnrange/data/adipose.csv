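# material: adipose
# density_g_cm3: 0.95
# composition (mass fractions): H=0.114, C=0.598, N=0.007, O=0.278, Na=0.001, S=0.001, Cl=0.001
# provenance: scripts/build_material_tables.py (elemental anchors + Klein-Nishina; reference-table agreement ~few %)
# columns: energy_keV, pe_cm2g, compton_cm2g, rayleigh_cm2g, mu_en_cm2g
energy_keV,pe_cm2g,compton_cm2g,rayleigh_cm2g,mu_en_cm2g
10.00,2.940547e+00,1.756929e-01,1.520964e-01,2.943844e+00
10.50,2.511794e+00,1.770182e-01,1.424011e-01,2.515274e+00
11.00,2.161349e+00,1.782048e-01,1.337330e-01,2.165012e+00
11.50,1.872266e+00,1.792692e-01,1.259438e-01,1.876111e+00
12.00,1.631792e+00,1.802254e-01,1.189116e-01,1.635817e+00
12.50,1.430211e+00,1.810853e-01,1.125357e-01,1.434415e+00
13.00,1.260033e+00,1.818592e-01,1.067322e-01,1.264415e+00
13.50,1.115425e+00,1.825562e-01,1.014304e-01,1.119984e+00
14.00,9.918021e-01,1.831838e-01,9.657084e-02,9.965365e-01
14.50,8.855237e-01,1.837488e-01,9.210264e-02,8.904324e-01
15.00,7.936783e-01,1.842572e-01,8.798237e-02,7.987601e-01
15.50,7.139183e-01,1.847143e-01,8.417267e-02,7.191720e-01
16.00,6.443372e-01,1.851245e-01,8.064118e-02,6.497614e-01
16.50,5.833760e-01,1.854921e-01,7.735984e-02,5.889697e-01
17.00,5.297522e-01,1.858206e-01,7.430411e-02,5.355142e-01
17.50,4.824043e-01,1.861133e-01,7.145251e-02,4.883332e-01
18.00,4.404486e-01,1.863731e-01,6.878615e-02,4.465434e-01
18.50,4.031458e-01,1.866027e-01,6.628832e-02,4.094053e-01
19.00,3.698744e-01,1.868044e-01,6.394425e-02,3.762973e-01
19.50,3.401091e-01,1.869803e-01,6.174079e-02,3.466942e-01
20.00,3.134043e-01,1.871324e-01,5.966620e-02,3.201505e-01
20.50,2.893801e-01,1.872624e-01,5.771001e-02,2.962862e-01
21.00,2.677116e-01,1.873719e-01,5.586282e-02,2.747764e-01
21.50,2.481197e-01,1.874624e-01,5.411616e-02,2.553421e-01
22.00,2.303638e-01,1.875352e-01,5.246241e-02,2.377427e-01
22.50,2.142358e-01,1.875914e-01,5.089469e-02,2.217700e-01
23.00,1.995550e-01,1.876323e-01,4.940675e-02,2.072434e-01
23.50,1.861644e-01,1.876588e-01,4.799293e-02,1.940058e-01
24.00,1.739264e-01,1.876719e-01,4.664807e-02,1.819199e-01
24.50,1.627210e-01,1.876724e-01,4.536748e-02,1.708653e-01
25.00,1.524425e-01,1.876612e-01,4.414686e-02,1.607366e-01
25.50,1.429980e-01,1.876389e-01,4.298230e-02,1.514407e-01
26.00,1.343053e-01,1.876064e-01,4.187018e-02,1.428956e-01
26.50,1.262918e-01,1.875641e-01,4.080721e-02,1.350287e-01
27.00,1.188931e-01,1.875127e-01,3.979035e-02,1.277755e-01
27.50,1.120520e-01,1.874527e-01,3.881680e-02,1.210787e-01
28.00,1.057173e-01,1.873846e-01,3.788397e-02,1.148874e-01
28.50,9.984356e-02,1.873090e-01,3.698949e-02,1.091560e-01
29.00,9.438998e-02,1.872262e-01,3.613113e-02,1.038438e-01
29.50,8.932001e-02,1.871367e-01,3.530686e-02,9.891412e-02
30.00,8.460085e-02,1.870409e-01,3.451479e-02,9.433426e-02
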