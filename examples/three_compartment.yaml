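# Heterogeneous three-compartment phantom (water / adipose / muscle)
# irradiated with the 100 kV beam; reports mean dose per compartment.
beam:
  kvp: 100
  ssd_cm: 30
  aperture: [circle, 4.0]
spectrum:
  kvp: 100
  filtration: [[Cu, 0.1], [Al, 0.5]]
phantom:
  type: three_compartment
  materials: [water, adipose, muscle]
run:
  histories: 60000
  seed: 1
normalize:
  output_gy_per_mu: 0.01
  mu: 100
  water_surface_dose: 1.0e-14
analyses:
  - compartment_means
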