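# Photon interaction coefficients for water
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       5.329        4.96444      4.944       
15       1.673        1.50427      1.374       
20       0.8096       0.711918     0.5503      
30       0.3756       0.330389     0.1557      
40       0.2683       0.242127     0.06947     
50       0.2269       0.209771     0.04223     
60       0.2059       0.193786     0.0319      
80       0.1837       0.176687     0.02597     
100      0.1707       0.16611      0.02546     
150      0.1505       0.148376     0.02764     
200      0.137        0.13577      0.02967     
300      0.1186       0.118031     0.03192     
400      0.1061       0.10577      0.03279     
500      0.09687      0.0966544    0.03299     
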