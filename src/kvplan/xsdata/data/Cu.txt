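# Photon interaction coefficients for Cu
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       215.9        211.016      148.4       
15       74.05        71.7894      57.88       
20       33.79        32.4813      25.68       
30       10.92        10.3143      8.162       
40       4.862        4.51135      3.367       
50       2.613        2.38352      1.662       
60       1.593        1.43071      0.9374      
80       0.763        0.669045     0.3816      
100      0.4584       0.396912     0.216       
150      0.2217       0.193241     0.0921      
200      0.1559       0.139425     0.05927     
300      0.1119       0.104275     0.03635     
400      0.09413      0.0897156    0.03139     
500      0.08362      0.080731     0.02968     
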