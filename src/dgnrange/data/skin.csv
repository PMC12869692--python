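# material: skin
# density_g_cm3: 1.09
# composition (mass fractions): H=0.1, C=0.204, N=0.042, O=0.645, Na=0.002, P=0.001, S=0.002, Cl=0.003, K=0.001
# provenance: scripts/build_material_tables.py (elemental anchors + Klein-Nishina; reference-table agreement ~few %)
# columns: energy_keV, pe_cm2g, compton_cm2g, rayleigh_cm2g, mu_en_cm2g
energy_keV,pe_cm2g,compton_cm2g,rayleigh_cm2g,mu_en_cm2g
10.00,4.620268e+00,1.699993e-01,1.928002e-01,4.623458e+00
10.50,3.949077e+00,1.714466e-01,1.805103e-01,3.952448e+00
11.00,3.400137e+00,1.727472e-01,1.695225e-01,3.403687e+00
11.50,2.947049e+00,1.739184e-01,1.596487e-01,2.950779e+00
12.00,2.569937e+00,1.749748e-01,1.507346e-01,2.573844e+00
12.50,2.253646e+00,1.759290e-01,1.426524e-01,2.257730e+00
13.00,1.986491e+00,1.767918e-01,1.352957e-01,1.990751e+00
13.50,1.759366e+00,1.775725e-01,1.285751e-01,1.763800e+00
14.00,1.565106e+00,1.782793e-01,1.224150e-01,1.569714e+00
14.50,1.398026e+00,1.789194e-01,1.167510e-01,1.402805e+00
15.00,1.253571e+00,1.794990e-01,1.115281e-01,1.258521e+00
15.50,1.128070e+00,1.800235e-01,1.066989e-01,1.133191e+00
16.00,1.018540e+00,1.804980e-01,1.022223e-01,1.023829e+00
16.50,9.225409e-01,1.809268e-01,9.806279e-02,9.279969e-01
17.00,8.380631e-01,1.813136e-01,9.418929e-02,8.436853e-01
17.50,7.634439e-01,1.816620e-01,9.057455e-02,7.692311e-01
18.00,6.972984e-01,1.819751e-01,8.719462e-02,7.032494e-01
18.50,6.384675e-01,1.822556e-01,8.402833e-02,6.445811e-01
19.00,5.859762e-01,1.825061e-01,8.105694e-02,5.922513e-01
19.50,5.390006e-01,1.827288e-01,7.826378e-02,5.454360e-01
20.00,4.968410e-01,1.829258e-01,7.563400e-02,5.034355e-01
20.50,4.589012e-01,1.830990e-01,7.315430e-02,4.656538e-01
21.00,4.246709e-01,1.832501e-01,7.081276e-02,4.315803e-01
21.50,3.937115e-01,1.833805e-01,6.859866e-02,4.007767e-01
22.00,3.656450e-01,1.834918e-01,6.650234e-02,3.728648e-01
22.50,3.401442e-01,1.835852e-01,6.451507e-02,3.475175e-01
23.00,3.169252e-01,1.836619e-01,6.262893e-02,3.244509e-01
23.50,2.957405e-01,1.837231e-01,6.083674e-02,3.034175e-01
24.00,2.763743e-01,1.837696e-01,5.913198e-02,2.842015e-01
24.50,2.586373e-01,1.838025e-01,5.750867e-02,2.666136e-01
25.00,2.423631e-01,1.838226e-01,5.596140e-02,2.504875e-01
25.50,2.274056e-01,1.838307e-01,5.448517e-02,2.356769e-01
26.00,2.136352e-01,1.838275e-01,5.307543e-02,2.220525e-01
26.50,2.009377e-01,1.838138e-01,5.172799e-02,2.094999e-01
27.00,1.892116e-01,1.837900e-01,5.043900e-02,1.979175e-01
27.50,1.783664e-01,1.837569e-01,4.920491e-02,1.872152e-01
28.00,1.683218e-01,1.837150e-01,4.802244e-02,1.773124e-01
28.50,1.590060e-01,1.836647e-01,4.688857e-02,1.681373e-01
29.00,1.503545e-01,1.836067e-01,4.580050e-02,1.596256e-01
29.50,1.423099e-01,1.835412e-01,4.475565e-02,1.517197e-01
30.00,1.348202e-01,1.834687e-01,4.375159e-02,1.443677e-01
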