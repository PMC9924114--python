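# Photon interaction coefficients for Au
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       113.7        103          103         
12       186          168          168         
15       148          132.824      130         
20       76           67.2145      67          
30       26           22.5         22.5        
40       12.3         10.7         10.7        
50       6.9          5.98         5.98        
60       4.34         3.69         3.69        
80.71    2.047        1.717        1.717       
80.73    8.9          8.28005      3.4         
100      5.158        4.74521      2.08        
150      1.86         1.66895      0.94        
200      0.9219       0.811297     0.5         
300      0.3803       0.329109     0.21        
400      0.2238       0.194165     0.125       
500      0.1582       0.138805     0.087       
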