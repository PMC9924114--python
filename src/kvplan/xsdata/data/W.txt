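# Photon interaction coefficients for W
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       96.91        89           89          
10.3     228          208          208         
12       210          190          190         
13       180          163          163         
15       139          126          126         
20       65.73        59.8         59.8        
30       22.73        20.5         20.5        
40       10.67        9.5          9.5         
50       5.949        5.2          5.2         
60       3.713        3.18         3.18        
69.51    2.552        2.12         2.12        
69.54    11.23        10.503       4           
80       7.81         7.25294      3.76        
100      4.438        4.07344      2.302       
150      1.581        1.41227      0.98        
200      0.7844       0.686718     0.53        
300      0.3238       0.278589     0.22        
400      0.1925       0.166327     0.13        
500      0.1378       0.120671     0.091       
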