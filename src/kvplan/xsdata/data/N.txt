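# Photon interaction coefficients for N
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       3.879        3.55097      3.545       
15       1.236        1.08417      1.083       
20       0.6178       0.529905     0.4204      
30       0.3066       0.265919     0.1172      
40       0.2288       0.205249     0.05327     
50       0.198        0.182587     0.03402     
60       0.1817       0.1708       0.0262      
80       0.1639       0.15759      0.0223      
100      0.1529       0.14877      0.0224      
150      0.1353       0.133389     0.02473     
200      0.1233       0.122193     0.02665     
300      0.1068       0.106288     0.02872     
400      0.09557      0.0952735    0.02949     
500      0.08719      0.086996     0.02966     
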