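# Photon interaction coefficients for C
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       2.373        2.12825      2.078       
15       0.8071       0.693822     0.5627      
20       0.442        0.376421     0.2238      
30       0.2562       0.225848     0.06614     
40       0.2076       0.190029     0.03343     
50       0.1871       0.175601     0.02397     
60       0.1753       0.167167     0.02098     
80       0.161        0.156292     0.02037     
100      0.1514       0.148319     0.02147     
150      0.1347       0.133274     0.02449     
200      0.1229       0.122074     0.02655     
300      0.1066       0.106218     0.0287      
400      0.09546      0.0952388    0.0295      
500      0.08715      0.0870052    0.02969     
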