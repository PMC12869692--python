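# material: csi
# density_g_cm3: 4.51
# composition (mass fractions): Cs=0.5115, I=0.4885
# provenance: scripts/build_material_tables.py (elemental anchors + Klein-Nishina; reference-table agreement ~few %)
# columns: energy_keV, pe_cm2g, compton_cm2g, rayleigh_cm2g, mu_en_cm2g
energy_keV,pe_cm2g,compton_cm2g,rayleigh_cm2g,mu_en_cm2g
10.00,1.662849e+02,6.173115e-02,1.950957e+00,1.579718e+02
10.50,1.454060e+02,6.448278e-02,1.826595e+00,1.381369e+02
11.00,1.279449e+02,6.707973e-02,1.715409e+00,1.215490e+02
11.50,1.132228e+02,6.953142e-02,1.615495e+00,1.075631e+02
12.00,1.007174e+02,7.184691e-02,1.525292e+00,9.568312e+01
12.50,9.002234e+01,7.403483e-02,1.443508e+00,8.552294e+01
13.00,8.081810e+01,7.610333e-02,1.369065e+00,7.677903e+01
13.50,7.285091e+01,7.806006e-02,1.301059e+00,6.921031e+01
14.00,6.591750e+01,7.991218e-02,1.238725e+00,6.262369e+01
14.50,5.985368e+01,8.166635e-02,1.181411e+00,5.686318e+01
15.00,5.452578e+01,8.332879e-02,1.128560e+00,5.180179e+01
15.50,4.982424e+01,8.490524e-02,1.079692e+00,4.733544e+01
16.00,4.565863e+01,8.640107e-02,1.034393e+00,4.337823e+01
16.50,4.195387e+01,8.782124e-02,9.923033e-01,3.985882e+01
17.00,3.864722e+01,8.917035e-02,9.531071e-01,3.671763e+01
17.50,3.568603e+01,9.045268e-02,9.165294e-01,3.390461e+01
18.00,3.302581e+01,9.167220e-02,8.823276e-01,3.137752e+01
18.50,3.062884e+01,9.283258e-02,8.502877e-01,2.910051e+01
19.00,2.846298e+01,9.393725e-02,8.202201e-01,2.704307e+01
19.50,2.650072e+01,9.498939e-02,7.919559e-01,2.517903e+01
20.00,2.471840e+01,9.599196e-02,7.653450e-01,2.348594e+01
20.50,2.309563e+01,9.694771e-02,7.402528e-01,2.194442e+01
21.00,2.161473e+01,9.785922e-02,7.165586e-01,2.053768e+01
21.50,2.026036e+01,9.872888e-02,6.941540e-01,1.925114e+01
22.00,1.901912e+01,9.955891e-02,6.729412e-01,1.807208e+01
22.50,1.787932e+01,1.003514e-01,6.528319e-01,1.698938e+01
23.00,1.683067e+01,1.011083e-01,6.337459e-01,1.599328e+01
23.50,1.586413e+01,1.018315e-01,6.156107e-01,1.507518e+01
24.00,1.497173e+01,1.025226e-01,5.983600e-01,1.422751e+01
24.50,1.414641e+01,1.031832e-01,5.819337e-01,1.344356e+01
25.00,1.338190e+01,1.038149e-01,5.662768e-01,1.271739e+01
25.50,1.267265e+01,1.044191e-01,5.513387e-01,1.204371e+01
26.00,1.201368e+01,1.049970e-01,5.370735e-01,1.141781e+01
26.50,1.140057e+01,1.055500e-01,5.234387e-01,1.083546e+01
27.00,1.082935e+01,1.060791e-01,5.103953e-01,1.029291e+01
27.50,1.029646e+01,1.065856e-01,4.979074e-01,9.786770e+00
28.00,9.798695e+00,1.070704e-01,4.859420e-01,9.314000e+00
28.50,9.333177e+00,1.075345e-01,4.744683e-01,8.871864e+00
29.00,8.897302e+00,1.079788e-01,4.634581e-01,8.457890e+00
29.50,8.488722e+00,1.084043e-01,4.528851e-01,8.069843e+00
30.00,8.105306e+00,1.088117e-01,4.427250e-01,7.705703e+00
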