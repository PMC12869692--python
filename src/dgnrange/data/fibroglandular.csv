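# material: fibroglandular
# density_g_cm3: 1.02
# composition (mass fractions): H=0.102, C=0.184, N=0.032, O=0.677, Na=0.001, P=0.001, S=0.001, Cl=0.001, K=0.001
# provenance: scripts/build_material_tables.py (elemental anchors + Klein-Nishina; reference-table agreement ~few %)
# columns: energy_keV, pe_cm2g, compton_cm2g, rayleigh_cm2g, mu_en_cm2g
energy_keV,pe_cm2g,compton_cm2g,rayleigh_cm2g,mu_en_cm2g
10.00,4.566514e+00,1.703430e-01,1.934900e-01,4.569710e+00
10.50,3.902756e+00,1.717923e-01,1.811561e-01,3.906133e+00
11.00,3.359945e+00,1.730948e-01,1.701290e-01,3.363503e+00
11.50,2.911956e+00,1.742677e-01,1.602199e-01,2.915693e+00
12.00,2.539119e+00,1.753256e-01,1.512739e-01,2.543035e+00
12.50,2.226439e+00,1.762811e-01,1.431628e-01,2.230532e+00
13.00,1.962355e+00,1.771451e-01,1.357798e-01,1.966624e+00
13.50,1.737858e+00,1.779269e-01,1.290351e-01,1.742301e+00
14.00,1.545860e+00,1.786347e-01,1.228530e-01,1.550477e+00
14.50,1.380736e+00,1.792757e-01,1.171687e-01,1.385525e+00
15.00,1.237982e+00,1.798560e-01,1.119271e-01,1.242943e+00
15.50,1.113968e+00,1.803813e-01,1.070806e-01,1.119099e+00
16.00,1.005742e+00,1.808564e-01,1.025880e-01,1.011042e+00
16.50,9.108919e-01,1.812857e-01,9.841363e-02,9.163588e-01
17.00,8.274303e-01,1.816730e-01,9.452628e-02,8.330636e-01
17.50,7.537130e-01,1.820218e-01,9.089861e-02,7.595116e-01
18.00,6.883707e-01,1.823352e-01,8.750658e-02,6.943334e-01
18.50,6.302575e-01,1.826161e-01,8.432896e-02,6.363832e-01
19.00,5.784093e-01,1.828668e-01,8.134694e-02,5.846968e-01
19.50,5.320117e-01,1.830898e-01,7.854379e-02,5.384598e-01
20.00,4.903730e-01,1.832870e-01,7.590460e-02,4.969806e-01
20.50,4.529039e-01,1.834603e-01,7.341603e-02,4.596698e-01
21.00,4.190999e-01,1.836115e-01,7.106611e-02,4.260230e-01
21.50,3.885276e-01,1.837420e-01,6.884409e-02,3.956067e-01
22.00,3.608134e-01,1.838533e-01,6.674027e-02,3.680474e-01
22.50,3.356338e-01,1.839467e-01,6.474589e-02,3.430216e-01
23.00,3.127082e-01,1.840235e-01,6.285300e-02,3.202487e-01
23.50,2.917923e-01,1.840846e-01,6.105440e-02,2.994844e-01
24.00,2.726726e-01,1.841311e-01,5.934354e-02,2.805152e-01
24.50,2.551620e-01,1.841639e-01,5.771443e-02,2.631540e-01
25.00,2.390964e-01,1.841839e-01,5.616161e-02,2.472367e-01
25.50,2.243310e-01,1.841919e-01,5.468011e-02,2.326186e-01
26.00,2.107382e-01,1.841886e-01,5.326532e-02,2.191720e-01
26.50,1.982049e-01,1.841747e-01,5.191306e-02,2.067839e-01
27.00,1.866308e-01,1.841508e-01,5.061946e-02,1.953539e-01
27.50,1.759267e-01,1.841175e-01,4.938095e-02,1.847929e-01
28.00,1.660132e-01,1.840754e-01,4.819425e-02,1.750214e-01
28.50,1.568192e-01,1.840249e-01,4.705633e-02,1.659684e-01
29.00,1.482812e-01,1.839666e-01,4.596437e-02,1.575704e-01
29.50,1.403424e-01,1.839009e-01,4.491577e-02,1.497706e-01
30.00,1.329515e-01,1.838282e-01,4.390813e-02,1.425177e-01
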