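# Photon interaction coefficients for Pb
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       130.6        123          123         
13.02    59           55           55          
13.05    161          141          141         
15       111.6        95.3106      95          
20       86.36        76.9298      68          
30       30.32        25.9554      24.7        
40       14.36        11.8332      11.7        
50       8.041        6.4328       6.4         
60       5.021        4.0168       4           
80       2.419        1.9352       1.92        
87.99    1.91         1.528        1.5         
88.01    7.683        7.11823      2.28        
100      5.549        5.10592      2.16        
150      2.014        1.80893      1.03        
200      0.9985       0.879781     0.587       
300      0.4031       0.348152     0.245       
400      0.2323       0.20049      0.145       
500      0.1614       0.140582     0.098       
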