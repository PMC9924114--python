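# Photon interaction coefficients for O
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       5.952        5.565        5.565       
15       1.836        1.64033      1.545       
20       0.8651       0.751822     0.6179      
30       0.3779       0.325471     0.1729      
40       0.2585       0.228148     0.0753      
50       0.2132       0.193336     0.04414     
60       0.1907       0.176652     0.03207     
80       0.1678       0.159667     0.02468     
100      0.1551       0.149778     0.02355     
150      0.1361       0.133637     0.02506     
200      0.1237       0.122274     0.02679     
300      0.107        0.10634      0.02877     
400      0.09566      0.0952779    0.02953     
500      0.08729      0.0870399    0.02971     
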