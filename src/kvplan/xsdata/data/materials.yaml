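# Materials registry: elemental composition (atomic number -> mass fraction),
# nominal density (g/cm^3), and the vendored coefficient table for each
# material.  Tissue compositions follow the ICRU-44-style reference tissues;
# air/metal compositions and densities follow the common Monte Carlo material
# databases.  `fixed_density: true` marks materials whose density is never
# taken from a HU-density curve during segmentation.
- name: air
  table: air
  density: 0.0012048
  fixed_density: true
  composition: {6: 0.000124, 7: 0.755268, 8: 0.231781, 18: 0.012827}
- name: water
  table: water
  density: 1.0
  composition: {1: 0.111894, 8: 0.888106}
- name: Al
  table: Al
  density: 2.699
  composition: {13: 1.0}
- name: Cu
  table: Cu
  density: 8.96
  composition: {29: 1.0}
- name: Sn
  table: Sn
  density: 7.31
  composition: {50: 1.0}
- name: W
  table: W
  density: 19.30
  composition: {74: 1.0}
- name: Pb
  table: Pb
  density: 11.35
  fixed_density: true
  composition: {82: 1.0}
- name: Au
  table: Au
  density: 19.32
  fixed_density: true
  composition: {79: 1.0}
- name: adipose
  table: adipose
  density: 0.95
  composition: {1: 0.114, 6: 0.598, 7: 0.007, 8: 0.278, 11: 0.001, 16: 0.001, 17: 0.001}
- name: muscle
  table: muscle
  density: 1.05
  composition: {1: 0.102, 6: 0.143, 7: 0.034, 8: 0.710, 11: 0.001, 15: 0.002, 16: 0.003, 17: 0.001, 19: 0.004}
- name: bone_cortical
  table: bone_cortical
  density: 1.92
  composition: {1: 0.034, 6: 0.155, 7: 0.042, 8: 0.435, 11: 0.001, 12: 0.002, 15: 0.103, 16: 0.003, 20: 0.225}
- name: lung
  table: lung
  density: 0.26
  composition: {1: 0.103, 6: 0.105, 7: 0.031, 8: 0.749, 11: 0.002, 15: 0.002, 16: 0.003, 17: 0.003, 19: 0.002}
- name: soft_tissue
  table: muscle
  density: 1.03
  composition: {1: 0.102, 6: 0.143, 7: 0.034, 8: 0.710, 11: 0.001, 15: 0.002, 16: 0.003, 17: 0.001, 19: 0.004}
- name: bone_trabecular
  table: bone_cortical
  density: 1.18
  composition: {1: 0.034, 6: 0.155, 7: 0.042, 8: 0.435, 11: 0.001, 12: 0.002, 15: 0.103, 16: 0.003, 20: 0.225}
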