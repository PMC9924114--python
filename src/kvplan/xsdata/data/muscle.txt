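# Photon interaction coefficients for muscle
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       5.356        4.98202      4.964       
15       1.693        1.51991      1.396       
20       0.8205       0.720294     0.5638      
30       0.3783       0.331921     0.161       
40       0.2685       0.241651     0.07192     
50       0.2262       0.208629     0.04349     
60       0.2048       0.192373     0.03258     
80       0.1823       0.175106     0.02615     
100      0.1693       0.164592     0.02544     
150      0.1492       0.147021     0.02745     
200      0.1358       0.134538     0.02942     
300      0.1175       0.116916     0.03164     
400      0.1051       0.104762     0.0325      
500      0.09599      0.0957688    0.03269     
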