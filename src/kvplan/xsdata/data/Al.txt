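# Photon interaction coefficients for Al
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       26.23        25.43        25.43       
15       7.955        7.487        7.487       
20       3.441        3.15605      3.094       
30       1.128        0.996115     0.8778      
40       0.5685       0.49215      0.3601      
50       0.3681       0.318133     0.184       
60       0.2778       0.242462     0.1099      
80       0.2018       0.181342     0.05511     
100      0.1704       0.157012     0.03794     
150      0.1378       0.131603     0.02827     
200      0.1223       0.118713     0.02745     
300      0.1042       0.10254      0.02816     
400      0.09276      0.0917988    0.02862     
500      0.08445      0.083821     0.02868     
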