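# Photon interaction coefficients for air
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       5.12         4.742        4.742       
15       1.614        1.4365       1.334       
20       0.7779       0.675141     0.5389      
30       0.3538       0.306239     0.1537      
40       0.2485       0.220966     0.06833     
50       0.208        0.189981     0.04098     
60       0.1875       0.174756     0.03041     
80       0.1662       0.158823     0.02407     
100      0.1541       0.149272     0.02325     
150      0.1356       0.133365     0.02496     
200      0.1233       0.122006     0.02672     
300      0.1067       0.106101     0.02872     
400      0.09549      0.0951434    0.02949     
500      0.08712      0.0868932    0.02966     
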