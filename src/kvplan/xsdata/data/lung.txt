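# Photon interaction coefficients for lung
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       5.413        5.03902      5.011       
15       1.712        1.53891      1.409       
20       0.8287       0.728494     0.5683      
30       0.3812       0.334821     0.1619      
40       0.2701       0.243251     0.0722      
50       0.2272       0.209629     0.0436      
60       0.2056       0.193173     0.03264     
80       0.1829       0.175706     0.02618     
100      0.1699       0.165192     0.02546     
150      0.1497       0.147521     0.02748     
200      0.1363       0.135038     0.02946     
300      0.1179       0.117316     0.03169     
400      0.1054       0.105062     0.03256     
500      0.09633      0.0961088    0.03275     
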