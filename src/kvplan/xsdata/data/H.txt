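# Photon interaction coefficients for H
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       0.3854       0.377267     0.00986     
15       0.3764       0.372636     0.011       
20       0.3695       0.367321     0.01331     
30       0.357        0.355991     0.01805     
40       0.3458       0.345216     0.02315     
50       0.3355       0.335118     0.02709     
60       0.326        0.32573      0.03053     
80       0.3091       0.308944     0.0362      
100      0.2944       0.294298     0.04063     
150      0.2651       0.265053     0.04813     
200      0.2429       0.242873     0.05254     
300      0.2112       0.211187     0.05695     
400      0.1893       0.189293     0.0586      
500      0.1729       0.172895     0.059       
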