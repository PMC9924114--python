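# Photon interaction coefficients for Sn
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       140.2        126.451      124         
15       47.68        43           43          
20       21.48        19.2         19.2        
29.19    7.76         6.9          6.9         
29.21    38.83        37.0362      12.6        
30       36.32        34.6149      11.9        
40       16.5         15.5129      6.2         
50       9.1          8.454        3.9         
60       5.68         5.22313      2.62        
80       2.652        2.38751      1.366       
100      1.676        1.50291      0.8301      
150      0.6091       0.528987     0.2866      
200      0.3354       0.289021     0.1496      
300      0.1734       0.151934     0.06819     
400      0.1193       0.106873     0.04699     
500      0.09405      0.0859173    0.03869     
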