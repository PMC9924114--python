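# End-to-end style run with the concave "C" lead cutout shape on a
# 10 cm circle applicator.
beam:
  applicator: 100H
  cutout:
    shape: C
    size_cm: 6.0
spectrum:
  kvp: 100
  filtration: [[Cu, 0.1], [Al, 0.5]]
phantom:
  type: watertank
  size_cm: [16, 16, 8]
  voxel_mm: [4, 4, 4]
run:
  histories: 40000
  seed: 1
analyses:
  - pdd
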