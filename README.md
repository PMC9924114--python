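# kvplan

A kilovoltage (kV) radiotherapy planning toolkit for medical physicists who
need Monte Carlo dose calculation for orthovoltage treatment units but have no
commercial treatment planning system that supports them. kvplan models the
whole clinical chain on a desk scale: x-ray tube spectra and beam quality
(HVL), applicators and custom lead cutouts, CT-style phantom segmentation,
voxel Monte Carlo photon dose calculation, absolute dose normalization against
the machine output, and the comparison analytics used to commission such a
system (PDD, profiles, output factors, backscatter factors, gamma index, DVH).

## Physics

**Spectra and beam quality.** Tube spectra are a parameterized Kramers
bremsstrahlung continuum with anode self-filtration, inherent filtration, and
tungsten K lines; measured/tabulated spectra can be loaded instead. The
half-value layer solves the discrete air-kerma ratio

```
K(t)/K(0) = Σᵢ (μen/ρ)ᵢ Eᵢ φᵢ exp(−(μᵢ_abs − μᵢ_air) t) ΔEᵢ
            / Σᵢ (μen/ρ)ᵢ Eᵢ φᵢ ΔEᵢ  =  1/2
```

by bracketing and bisection, with the absorber attenuation corrected for the
air it displaces.

**Backscatter factor.** From in-air and backscattered fluence spectra,

```
B_w = Σ (φ_air + φ_scatter) E (μen/ρ)_w ΔE / Σ φ_air E (μen/ρ)_w ΔE ,
```

with the two spectra scored by paired transport runs (water phantom present /
absent behind the surface plane).

**Transport.** Photons are tracked by Woodcock (delta) tracking through the
voxel phantom; interaction channels (photoelectric / Compton / Rayleigh) are
chosen from vendored cross-section tables, Compton scattering samples the
Klein–Nishina distribution, and dose is scored as collision kerma — secondary
electrons at kV energies have sub-voxel ranges, so kerma equals absorbed dose
to an excellent approximation. Runs are exactly reproducible for a fixed seed
and carry per-voxel statistical uncertainties from a batch estimator.

**Absolute dose.** A phantom simulation is normalized to absolute dose via
`D = D_sim_phantom / D_sim_water × O × MU` where `O` (Gy/MU) is the unit
output for the applicator, and chamber readings convert to dose through the
dose-to-water calibration coefficient `N_dw = D_w^MC / (M_w · (μen/ρ)ratio)`.

## Worked example

Beam quality of the 70 kV clinical beam (2 mm Al filtration):

```
$ kvplan hvl --kvp 70 --filtration "2Al"
HVL: 2.043 mm Al
```

Dose-to-water calibration coefficient from a heterogeneous-phantom
measurement — 0.63 Gy Monte Carlo dose in the water compartment, 1.135 nC
chamber reading, spectrum-weighted water/air mass energy-absorption ratio
1.0239:

```
$ kvplan calibrate --dose-mc 0.63 --reading 1.135 --muen-ratio 1.0239
N_dw: 0.542 Gy/nC
```

Multiplying `N_dw` by the adipose-compartment reading (1.33 nC) and the
adipose/air ratio (0.6346) gives a measured dose-to-medium of 0.457 Gy; the
muscle compartment (1.072 nC, 0.9962) gives 0.579 Gy.

A complete watertank plan (simulate, normalize to 100 MU at 0.01 Gy/MU,
extract PDD/profile/DVH) runs from a YAML config:

```
$ kvplan simulate examples/watertank.yaml --out-dir run1
outputs in run1
```

`run1/` then contains `dose.3ddose` (surface voxel reads exactly
O·MU = 1.0 Gy), `pdd.csv`, `profile_10mm.csv`, `dvh.csv`, and a
`manifest.json` recording version, seed, and config for reproducibility.

Python API:

```python
from kvplan import beams, dosimetry, spectrum, transport, phantom

sp = spectrum.filter_spectrum(spectrum.generate_tube_spectrum(100),
                              [("Cu", 0.1), ("Al", 0.5)])
beam = beams.BeamSetup(beams.get_applicator("100H"))  # 10 cm circle, SSD 30
bsf = dosimetry.bsf_from_simulation(beam, sp,
                                    transport.RunConfig(n_histories=100_000,
                                                        seed=1))
```

prints a backscatter factor near 1.37 for the 10 cm circle at 100 kV quality,
falling to about 1.13 for the 2 cm circle — the expected field-size trend.

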