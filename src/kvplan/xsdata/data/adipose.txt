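# Photon interaction coefficients for adipose
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       3.268        2.99948      2.918       
15       1.083        0.958719     0.824       
20       0.5578       0.485851     0.3341      
30       0.3063       0.273        0.09746     
40       0.2396       0.220322     0.0465      
50       0.2123       0.199684     0.0319      
60       0.1974       0.188477     0.02656     
80       0.179        0.173835     0.02411     
100      0.1665       0.16312      0.02453     
150      0.1474       0.145835     0.02703     
200      0.1343       0.133394     0.02918     
300      0.1165       0.116081     0.03146     
400      0.1043       0.104057     0.03232     
500      0.09523      0.0950712    0.03253     
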