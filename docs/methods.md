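# Methods

This note records the models implemented in kvplan, the defaults chosen where
the design was genuinely open, and what the tests do and do not demonstrate.

## Cross-section data (`kvplan.xsdata`)

Photon mass attenuation (μ/ρ, with and without the coherent contribution) and
mass energy-absorption (μen/ρ) coefficients are vendored as plain-text tables
on a 10–500 keV grid, transcribed from the standard published compilations,
with K-edge discontinuities represented by doubled knots (Sn 29.2 keV,
W 69.5 keV, Au 80.7 keV, Pb 88.0 keV). Two accuracy caveats are recorded in
every file header: the L-edge fine structure of the heavy metals below about
16 keV is smoothed, and the coherent-free column is derived by subtracting an
approximate power-law Rayleigh estimate (anchored to water at 30 keV, capped
at 20% of the total). The first caveat only shapes the soft tail of generated
tube spectra; the second only moves the Rayleigh/Compton split inside the
transport engine, not the total attenuation.

Interpolation is linear in (log E, log coefficient) — standard practice for
photon cross sections, exact at knots, and monotone between monotone knots.
No extrapolation: energies outside the table range raise. Mixtures without a
vendored table are built by elemental additivity (Σ wᵢ·coefficientᵢ); the
tissues (ICRU-44-style adipose, muscle, cortical bone, lung) ship as
compound tables with their compositions in the registry, since the
registry compositions are also needed for electron densities (Compton) in
transport.

## Tube spectrum model (`kvplan.spectrum`)

The spectrum generator is an analytical stand-in for a full electron-on-target
simulation:

- Kramers continuum, fluence per bin ∝ (kVp − E)/E;
- anode self-filtration through an effective tungsten path
  `t = f·R(E₀)/(ρ_W·sin θ_target)` where `R(E₀) = 4.1·10⁻⁶·E₀^1.75 g/cm²` is
  an empirical electron penetration for 40–300 keV electrons, `f = 0.5` the
  mean production-depth fraction, and θ_target = 30° the default target angle;
- inherent filtration default 0.1 mm Al equivalent (orthovoltage tubes have
  thin beryllium windows; Be is optically thin at these energies);
- tungsten K lines (57.98, 59.32, 67.24, 69.07 keV with relative weights
  58:100:33:11) above the 69.525 keV K edge, with total line fluence tied to
  the continuum by an overvoltage power law `(kVp/E_K − 1)^1.67` and a scale
  of 0.06.

These parameters were fixed from physical reasoning, not fitted to any HVL.
With the clinical filtrations (2 Al; 0.1 Cu + 0.5 Al; 0.2 Cu + 2.5 Al;
0.4 Sn + 0.25 Cu + 1 Al, mm) the model yields HVLs of 2.04, 4.27, 7.81 mm Al
and 1.82 mm Cu for 70/100/125/200 kVp — all within the 10% clinical beam
quality tolerance of typical commissioning values for such units. The HVL
solver brackets on [0, 50] mm (Al-like) or [0, 10] mm (Cu-like) and bisects
(Brent) to 10⁻⁶ relative on the kerma ratio; the attenuation exponent is
(μ_abs − μ_air)·t per the air-displacement convention, which matters at the
10⁻⁴ level for monoenergetic closed-form checks. Bin midpoints evaluate all
coefficients; default bin width 1 keV. Absorber impurities are not modeled —
tables are pure-element.

## Phantoms and segmentation (`kvplan.phantom`)

Segmentation schemes are ordered half-open [lo, hi) HU intervals that
partition the full supported range (−1024 to 40000 HU, metals at the top);
boundary HU belong to the higher interval, a deterministic tie-break. Three
editable site schemes ship (head-neck, torso, extremity); their breakpoints
are literature-typical commissioning values, not a universal calibration —
users should substitute local CT calibration data. Density comes from a
piecewise-linear HU-density curve (default through (−1000, 0.001),
(0, 1.000), (1500, 1.92), clamped; CSV-loadable), except that air, lead, and
gold always take nominal densities — a CT scanner's HU for metals is
meaningless for density. Out-of-range HU are clamped and counted.

Lead cutouts and internal shields enter a phantom by overwriting HU inside a
structure mask, exactly as the clinical workflow does; alternatively cutouts
act as perfect absorbers at the exit window (the default for the source
model). Both idealizations are offered because a voxelized lead slab blurs
the penumbra at the voxel scale while the perfect absorber sharpens it.

The phantom file is an egsphant-style text layout: material count and names;
nx ny nz; the three voxel-boundary coordinate lists (cm); one character per
voxel of material index (x fastest, one line per y-row, blank line between
z-slices); then density blocks in the same order. Round-trips are lossless to
6 significant digits.

## Beams and source model (`kvplan.beams`)

The applicator catalogue holds the clinical set of 49 energy–applicator
combinations: the reference applicators (10 cm circle at 30 cm SSD for
70/100/125 kV; 10×10 cm² at 50 cm SSD for 200 kV) are fixed, and the
remaining lettered entries are editable placeholders with plausible sizes —
their physical dimensions are site commissioning data.

The source is an analytic point source: positions uniform over the open part
of the exit-window aperture (rejection sampling in the cutout polygon),
directions diverging from the focal spot at SSD, energies from the discrete
spectrum distribution. A phase-space-like text format (`E x y z u v w wt`)
supports externally generated sources. The angle convention is spherical
polar: θ from +z, φ from +x, φ_col about the beam axis; (θ=0, φ=0) points
down +z, (θ=90°, φ=0) along +x.

Because the source spreads a fixed particle count over the aperture, dose per
source particle scales inversely with aperture area. Output factors between
different apertures therefore apply equal-fluence scaling (each dose
multiplied by its open aperture area); comparisons at one geometry need no
scaling.

## Transport engine (`kvplan.transport`)

Woodcock (delta) tracking against a per-energy majorant (the max over
materials of μ/ρ times that material's maximum voxel density, optionally
floored to force collisions in near-vacuum) avoids voxel-boundary ray
tracing and is exact in distribution. At real collisions the channel is
sampled from per-material fractions: Compton = Klein–Nishina per electron ×
electrons/g (from the registry composition), Rayleigh = total minus
coherent-free columns, photoelectric = remainder. Compton uses the standard
two-branch composition-rejection sampler; the scattered energy satisfies the
Compton relation exactly for the sampled angle. Rayleigh redirects with a
Thomson-shaped (1+cos²θ) law — form factors are out of scope, which
overestimates large-angle coherent scattering somewhat. Photons below the
5 keV default cutoff deposit locally and die; coefficients below the 10 keV
table floor reuse the floor values. Characteristic x-ray re-emission after
photoelectric absorption is neglected (a known small bias at these energies:
fluorescence below ~70 keV deposits near-locally anyway, except near metal
interfaces).

**Scoring.** Dose is collision kerma via the Woodcock collision-density
estimator: every collision, real or virtual, contributes
`w·E·(μen/ρ)·ρ/μ_maj` to its voxel. This is the kerma approximation —
secondary electron CSDA ranges at ≤ 200 keV are below the 2 mm default voxel
— and has far lower variance than analog deposition. Alongside, an exact
analog energy ledger (emitted = deposited + escaped, to float precision)
tracks conservation; note that even an arbitrarily large water phantom loses
20–25% of the emitted energy at 70–100 kV quality through backscatter out of
the entrance face, so "no escape" is an idealization no finite geometry
reaches. The kerma estimator and the analog ledger disagree by a few percent
in media where the μen tables and the sampled scatter model are not perfectly
consistent; the kerma estimate is the dosimetric quantity.

**Uncertainty and reproducibility.** A 10-batch standard-error estimator
gives per-voxel relative uncertainties; batch RNG streams are spawned from
the run seed (SeedSequence), so identical (seed, config, inputs) produce
bit-identical 3ddose files. Substreams are per batch rather than per history
— the vectorized engine processes whole batches, and per-batch spawning
preserves the reproducibility contract at far lower bookkeeping cost. With
10 batches the uncertainty of the uncertainty is ~22%, so tests that check
uncertainty scaling average it over voxel regions.

Dose files use the EGSnrc 3ddose text layout (shape line, three boundary
lists in cm, dose values with x fastest, then relative errors).

## Dosimetry (`kvplan.dosimetry`)

- **BSF**: the fluence-spectrum ratio above; the simulated route scores
  crossing spectra on a plane just inside the surface, restricted to a
  central disc (quarter of the aperture, capped at 1 cm radius) so the ratio
  is an on-axis quantity — integrating the whole plane would count scatter
  leaving far outside the field and destroy the field-size dependence.
  Fluence weighting divides by |direction cosine| capped at 50.
- **PDD**: central-axis column normalized to 100% at the first (surface)
  voxel layer; "surface dose" always means that first 2 mm voxel layer.
- **Profiles**: field width = distance between the 50%-of-center points;
  normalization region = central 80% of that width; values divided by the
  trapezoidal mean over the region. This reading of "area under the curve
  within the 80% profile width" is one of several defensible conventions and
  is flagged here deliberately.
- **Gamma**: global normalization to the reference maximum; points below the
  threshold (20% or 50% presets) are excluded; the search is exhaustive
  within 3 distance-criteria on an eval grid refined by linear interpolation
  (default 4×). Gamma is not symmetric in (reference, evaluated) — the
  reference defines threshold and normalization — and the suite tests that
  asymmetry on a constructed case.
- **Calibration**: `N_dw = D_w^MC/(M_w·ratio)`; the division convention is
  fixed by requiring the printed worked example to reproduce, and the
  downstream dose-to-medium chain uses the coefficient at its reported
  3-significant-figure precision, again matching how such chains are quoted
  in practice. Spectrum-weighted μen ratios are kerma-weighted averages over
  a supplied spectrum, with scalar overrides accepted wherever a measured
  ratio is preferred.
- **Percent difference**: (reference − test)/reference × 100, the only
  convention consistent with the full set of worked examples.

## Pipeline and CLI

The pipeline is file-based YAML (no GUI): segment → beam → transport →
normalization → analyses, with a JSON manifest (version, seed, config
snapshot, input hashes, timestamps) written beside every dose file. Config
errors name the failing field path. The `kvplan` command exposes hvl,
segment, simulate, bsf, pdd, profile, gamma, dvh, normalize, calibrate, and
validate-config.

## Problem sizes and what the tests show

The test and acceptance suites run at desk scale: 10⁴–2×10⁵ histories on
phantoms of order 50×50×50 voxels at 2–10 mm, chosen so each statistical
assertion has 3σ headroom at a few percent. Clinical-scale runs (10⁹
histories, sub-percent uncertainty) are the same code path, just longer.
Passing tests demonstrate internal physical consistency against closed-form
oracles (Beer–Lambert, inverse-square, fluence-to-kerma, Klein–Nishina
distribution, analytic HVLs) and correct trends (beam hardening, backscatter
vs field size, beam-quality ordering at depth); they do not demonstrate
agreement with any specific treatment unit, which requires commissioning
against measured beam data. The synthetic phantoms (watertank,
three-compartment, slab) emulate commissioning geometries; they contain no
CT noise, no partial-volume voxels, and no metal artifacts, so segmentation
robustness on real CT data is untested here.

## Known limitations

- No electron transport: dose is collision kerma. Fine at kV energies and
  2 mm voxels; wrong within ~1 voxel of metal interfaces.
- No Rayleigh form factors, no fluorescence re-emission, no
  bremsstrahlung in the phantom.
- The analytic tube model is a beam-quality surrogate, not a tube
  simulation: no heel effect, no off-axis softening, no applicator wall
  scatter (open-ended applicator walls are not modeled at all).
- Non-reference applicator dimensions are placeholders.
- The vendored cross sections carry transcription-level accuracy (worst for
  the heavy metals between 10 and 20 keV); all quantitative tests are
  internally consistent with these tables.
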