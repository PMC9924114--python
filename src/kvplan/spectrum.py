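"""kV photon spectra: generation, filtration, air kerma, and HVL.

The tube model is a parameterized analytical stand-in for a full
electron-on-target simulation: a Kramers bremsstrahlung continuum with anode
self-attenuation (effective tungsten path derived from the electron
penetration depth and the target angle), inherent filtration, and the
tungsten K fluorescence lines above the K edge.  It is deliberately simple --
its job is to provide realistic beam qualities for the downstream HVL,
backscatter and dose machinery, which also accept measured/tabulated spectra.

The half-value layer is solved from the discrete air-kerma ratio

    K(t)/K(0) = sum_i (muen/rho)_air,i E_i phi_i exp(-(mu_abs,i - mu_air,i) t) dE_i
                / sum_i (muen/rho)_air,i E_i phi_i dE_i  =  1/2,

i.e. attenuation by the absorber corrected for the air it displaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import xsdata

__all__ = [
    "Spectrum",
    "generate_tube_spectrum",
    "filter_spectrum",
    "air_kerma",
    "solve_hvl",
    "read_spectrum",
    "write_spectrum",
]

KEV_TO_JOULE = 1.602176634e-16
AIR_DENSITY = 0.0012048  # g/cm^3 at 20 C

# Tungsten K fluorescence: (energy keV, relative intensity)
W_K_LINES = ((57.98, 58.0), (59.32, 100.0), (67.24, 33.0), (69.07, 11.0))
W_K_EDGE = 69.525


@dataclass
class Spectrum:
    """Binned photon fluence spectrum (photons/cm^2 per source particle)."""

    bin_edges: np.ndarray  # keV, n+1 strictly increasing
    fluence: np.ndarray    # per bin, n values >= 0
    label: str = ""

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 3:
            raise ValueError("need at least 2 bins")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.fluence) != len(self.bin_edges) - 1:
            raise ValueError("fluence length must match bin count")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if not np.all(np.isfinite(self.fluence)):
            raise ValueError("fluence must be finite")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def mean_energy(self) -> float:
        """Fluence-weighted mean energy (keV)."""
        if self.total_fluence == 0:
            raise ValueError("empty spectrum has no mean energy")
        return float(np.sum(self.fluence * self.midpoints) / self.total_fluence)

    def normalized(self) -> "Spectrum":
        tot = self.total_fluence
        if tot == 0:
            raise ValueError("cannot normalize an empty spectrum")
        return Spectrum(self.bin_edges, self.fluence / tot, self.label)

    @classmethod
    def monoenergetic(cls, energy_kev: float, fluence: float = 1.0,
                      bin_width: float = 1.0) -> "Spectrum":
        """Two-bin spectrum with all fluence in the bin centred on `energy`."""
        edges = np.array([energy_kev - 1.5 * bin_width,
                          energy_kev - 0.5 * bin_width,
                          energy_kev + 0.5 * bin_width])
        return cls(edges, np.array([0.0, fluence]), f"mono-{energy_kev}keV")


@dataclass
class TubeConfig:
    """X-ray tube parameters for the analytical spectrum model."""

    target_angle_deg: float = 30.0
    focal_spot_mm: float = 7.0
    # mean photon production depth as a fraction of the electron penetration
    production_depth_fraction: float = 0.5
    # inherent filtration layers (material name, thickness mm); a beryllium
    # window is typical for orthovoltage tubes but Be is optically thin at
    # these energies, so the default carries a thin Al equivalent instead.
    inherent_filtration: tuple = (("Al", 0.1),)
    # K-line energy-fluence fraction scale (dimensionless)
    k_line_scale: float = 0.06


def _electron_range_gcm2(e0_kev: float) -> float:
    # empirical CSDA-like range in g/cm^2 for 40-300 keV electrons
    return 4.1e-6 * e0_kev**1.75


def generate_tube_spectrum(kvp: float, bin_width: float = 1.0,
                           config: TubeConfig | None = None,
                           target_angle: float | None = None) -> Spectrum:
    """Analytical kV tube spectrum at the given peak voltage.

    Kramers continuum ``phi(E) ~ (kvp - E)/E`` attenuated by the effective
    tungsten self-filtration path and the inherent filtration, plus tungsten
    K lines for kvp above the K edge.  Fluence is zero above `kvp`.
    """
    cfg = config or TubeConfig()
    if target_angle is not None:
        cfg = TubeConfig(**{**cfg.__dict__, "target_angle_deg": target_angle})
    if not 40.0 <= kvp <= 300.0:
        raise ValueError(f"kvp {kvp} outside supported 40-300 kV")
    n_bins = int(round(kvp / bin_width))
    if n_bins < 20:
        raise ValueError("bin_width too coarse: need at least 20 bins")
    edges = np.linspace(0.0, kvp, n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    fluence = np.zeros(n_bins)

    w_table = xsdata.get_table("W")
    rho_w = xsdata.get_material("W").nominal_density
    e_min = max(w_table.energies[0], 8.0)
    valid = (mid >= e_min) & (mid < kvp)

    # anode self-filtration: photons produced at a mean depth inside the
    # target escape through an oblique tungsten path set by the target angle
    depth_cm = (cfg.production_depth_fraction * _electron_range_gcm2(kvp)
                / rho_w)
    sin_t = np.sin(np.radians(cfg.target_angle_deg))
    path_cm = depth_cm / max(sin_t, 1e-3)

    e = mid[valid]
    kramers = (kvp - e) / e
    atten = np.exp(-w_table.mu(e) * rho_w * path_cm)
    fluence[valid] = kramers * atten
    spec = Spectrum(edges, fluence, f"{kvp:g}kVp")

    if kvp > W_K_EDGE:
        # K fluorescence: total K-line fluence tied to the continuum fluence
        # with an overvoltage scaling
        overvoltage = (kvp / W_K_EDGE - 1.0) ** 1.67
        total_lines = cfg.k_line_scale * overvoltage * spec.total_fluence
        weight_sum = sum(w for _, w in W_K_LINES)
        for e_line, w in W_K_LINES:
            idx = np.searchsorted(edges, e_line, side="right") - 1
            fluence[idx] += total_lines * w / weight_sum
        spec = Spectrum(edges, fluence, spec.label)

    return filter_spectrum(spec, list(cfg.inherent_filtration))


def filter_spectrum(spectrum: Spectrum, layers) -> Spectrum:
    """Attenuate a spectrum through (material, thickness mm) layers."""
    if not layers:
        return Spectrum(spectrum.bin_edges.copy(), spectrum.fluence.copy(),
                        spectrum.label)
    mid = spectrum.midpoints
    populated = spectrum.fluence > 0
    total_mu_t = np.zeros_like(mid)
    for material, thickness_mm in layers:
        if thickness_mm < 0:
            raise ValueError("negative filter thickness")
        mat = xsdata.get_material(material) if isinstance(material, str) \
            else material
        table = xsdata.get_table(mat.table_name or mat.name)
        mu_lin = np.zeros_like(mid)
        mu_lin[populated] = table.mu(mid[populated]) * mat.nominal_density
        total_mu_t += mu_lin * (thickness_mm / 10.0)
    out = spectrum.fluence * np.exp(-total_mu_t)
    label = spectrum.label + "+" + "".join(
        f"{t}{m if isinstance(m, str) else m.name}" for m, t in layers)
    return Spectrum(spectrum.bin_edges.copy(), out, label)


def air_kerma(spectrum: Spectrum) -> float:
    """Air kerma per source particle (Gy cm^2): sum of E phi (muen/rho) dE."""
    mid = spectrum.midpoints
    populated = spectrum.fluence > 0
    if not populated.any():
        return 0.0
    table = xsdata.get_table("air")
    muen = table.muen(mid[populated])  # cm^2/g
    e_j = mid[populated] * KEV_TO_JOULE
    # phi is per cm^2; muen/rho in cm^2/g -> *1000 g/kg gives Gy cm^2
    return float(np.sum(e_j * spectrum.fluence[populated] * muen * 1000.0))


def _kerma_ratio(spectrum: Spectrum, absorber_mat, absorber_table,
                 air_table, t_mm: float) -> float:
    mid = spectrum.midpoints
    populated = spectrum.fluence > 0
    e = mid[populated]
    muen_air = air_table.muen(e)
    w = spectrum.fluence[populated] * e * muen_air * spectrum.widths[populated]
    k0 = np.sum(w)
    mu_abs = absorber_table.mu(e) * absorber_mat.nominal_density
    mu_air = air_table.mu(e) * AIR_DENSITY
    kt = np.sum(w * np.exp(-(mu_abs - mu_air) * (t_mm / 10.0)))
    return kt / k0


def solve_hvl(spectrum: Spectrum, absorber="Al", max_thickness_mm: float | None = None,
              rtol: float = 1e-6) -> float:
    """Half-value layer (mm of absorber) of a spectrum.

    Bisects the absorber thickness until the air-kerma ratio reaches 1/2,
    attenuating each bin with the absorber's linear attenuation coefficient
    minus that of the displaced air.
    """
    mat = xsdata.get_material(absorber) if isinstance(absorber, str) else absorber
    table = xsdata.get_table(mat.table_name or mat.name)
    air_table = xsdata.get_table("air")
    if air_kerma(spectrum) <= 0:
        raise ValueError("spectrum has zero air kerma")
    if max_thickness_mm is None:
        max_thickness_mm = 50.0 if mat.nominal_density < 5 else 10.0

    def f(t):
        return _kerma_ratio(spectrum, mat, table, air_table, t) - 0.5

    if f(max_thickness_mm) > 0:
        raise RuntimeError(
            f"no HVL bracket below {max_thickness_mm} mm {mat.name}")
    return float(brentq(f, 0.0, max_thickness_mm, rtol=rtol, xtol=1e-9))


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Two-column text export: bin midpoint (keV) and fluence."""
    with open(path, "w") as fh:
        fh.write(f"# spectrum: {spectrum.label}\n")
        fh.write(f"# bin_width_keV: {spectrum.widths[0]:g}\n")
        fh.write("# E_mid_keV  fluence\n")
        for e, phi in zip(spectrum.midpoints, spectrum.fluence):
            fh.write(f"{e:.6g} {phi:.8g}\n")


def read_spectrum(path, label: str | None = None) -> Spectrum:
    """Read the two-column text format written by :func:`write_spectrum`."""
    mids, phis = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            e, phi = line.split()[:2]
            mids.append(float(e))
            phis.append(float(phi))
    mids = np.asarray(mids)
    phis = np.asarray(phis)
    if len(mids) < 2:
        raise ValueError("spectrum file needs at least 2 bins")
    width = np.diff(mids)
    if not np.allclose(width, width[0], rtol=1e-6):
        raise ValueError("spectrum file must be on a uniform grid")
    edges = np.concatenate([mids - width[0] / 2, [mids[-1] + width[0] / 2]])
    return Spectrum(edges, phis, label or str(path))
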