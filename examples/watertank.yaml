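# Reference watertank run: 100 kV, 10 cm circle applicator at 30 cm SSD,
# normalized to 100 MU at an output of 0.01 Gy/MU.
beam:
  applicator: 100H
spectrum:
  kvp: 100
  filtration: [[Cu, 0.1], [Al, 0.5]]
phantom:
  type: watertank
  size_cm: [20, 20, 15]
  voxel_mm: [4, 4, 4]
run:
  histories: 50000
  seed: 1
normalize:
  output_gy_per_mu: 0.01
  mu: 100
analyses:
  - pdd
  - type: profile
    depth_mm: 10
  - dvh
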