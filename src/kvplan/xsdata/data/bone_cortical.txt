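# Photon interaction coefficients for bone_cortical
# Transcribed from the standard published mass attenuation /
# mass energy-absorption compilations (Hubbell & Seltzer / XCOM grid).
# L-edge fine structure of heavy metals below ~16 keV is smoothed;
# the coherent-free column uses an approximate Rayleigh estimate.
# columns: E_keV  mu_rho  mu_rho_coherentless  muen_rho   [cm^2/g]
10       28.51        27.3188      26.8        
15       9.032        8.48065      8.388       
20       4.001        3.68181      3.601       
30       1.331        1.18327      1.07        
40       0.6655       0.579976     0.4507      
50       0.4242       0.368229     0.2336      
60       0.3148       0.275216     0.14        
80       0.2229       0.199984     0.06896     
100      0.1855       0.170503     0.04585     
150      0.148        0.141059     0.03183     
200      0.1309       0.126882     0.03003     
300      0.1113       0.10944      0.03032     
400      0.09908      0.0980033    0.03069     
500      0.09022      0.0895154    0.03073     
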