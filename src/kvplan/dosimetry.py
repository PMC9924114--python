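"""Derived dosimetric quantities and dose-distribution comparisons.

Covers the quantities a kV planning workflow reports: backscatter factors
from fluence spectra, percentage depth dose and lateral profiles, output
factors, absolute dose normalization against the machine output, the
dose-to-water calibration chain (charge reading -> dose via the
spectrum-weighted water/air mass energy-absorption ratio), percent
differences, the gamma index, and cumulative dose-volume histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import xsdata
from .phantom import StructureMask, VoxelPhantom
from .spectrum import Spectrum
from .transport import DoseGrid, RunConfig, run_simulation

__all__ = [
    "DepthCurve",
    "Profile",
    "GammaResult",
    "bsf_from_spectra",
    "bsf_from_simulation",
    "extract_pdd",
    "extract_profile",
    "output_factor",
    "absolute_dose",
    "calibration_coefficient",
    "dose_to_medium_from_reading",
    "percent_difference",
    "spectrum_weighted_muen_ratio",
    "gamma_index",
    "dvh",
]


# --- backscatter factor -----------------------------------------------------

def bsf_from_spectra(air: Spectrum, water_scatter: Spectrum) -> float:
    """Backscatter factor from in-air and backscattered fluence spectra.

    ``B_w = sum (phi_air + phi_scatter) E (muen/rho)_w dE
            / sum phi_air E (muen/rho)_w dE``:
    the ratio of water kerma at the surface with and without the
    backscattered fluence added to the primary in-air fluence.
    """
    if len(air.bin_edges) != len(water_scatter.bin_edges) or \
            not np.allclose(air.bin_edges, water_scatter.bin_edges):
        raise ValueError("spectra must share the same bin grid")
    mid = air.midpoints
    populated = (air.fluence > 0) | (water_scatter.fluence > 0)
    muen_w = xsdata.get_table("water").muen(mid[populated])
    w = mid[populated] * muen_w * air.widths[populated]
    primary = np.sum(air.fluence[populated] * w)
    if primary <= 0:
        raise ValueError("air spectrum has zero water kerma")
    total = np.sum((air.fluence + water_scatter.fluence)[populated] * w)
    return float(total / primary)


def bsf_from_simulation(beam, spectrum: Spectrum,
                        config: RunConfig | None = None,
                        water_depth_cm: float = 15.0,
                        lateral_cm: float = 30.0,
                        voxel_mm: float = 4.0) -> float:
    """Backscatter factor by paired transport runs.

    Runs the engine twice with a fluence tally plane at the phantom surface:
    once with a water phantom behind the plane and once with the water
    replaced by near-vacuum.  The primary (downward) spectrum of the
    vacuum run and the backscattered (upward) spectrum of the water run
    enter :func:`bsf_from_spectra`.  Stochastic.
    """
    from .phantom import make_watertank

    cfg = config or RunConfig(n_histories=50_000)
    water = make_watertank((lateral_cm, lateral_cm, water_depth_cm),
                           (voxel_mm, voxel_mm, voxel_mm))
    vacuum = make_watertank((lateral_cm, lateral_cm, water_depth_cm),
                            (voxel_mm, voxel_mm, voxel_mm))
    vacuum.density[:] = 1e-6

    plane_z = 0.05  # just inside the surface, cm
    # fluence scored in a central disc so the ratio is an on-axis quantity
    if beam.applicator.aperture[0] == "circle":
        radius = min(1.0, 0.25 * beam.applicator.aperture[1])
    else:
        radius = min(1.0, 0.25 * min(beam.applicator.aperture[1:]))
    extra = {"tally_plane_z_cm": plane_z, "tally_radius_cm": radius}
    run_w = run_simulation(water, beam, spectrum,
                           RunConfig(**{**cfg.__dict__, **extra}))
    with warnings.catch_warnings():
        # the no-backing run deposits almost nothing by construction
        warnings.simplefilter("ignore")
        run_v = run_simulation(vacuum, beam, spectrum,
                               RunConfig(**{**cfg.__dict__, **extra}))

    phi_air = run_v.tallies["plane_down"]
    phi_scatter = run_w.tallies["plane_up"]
    return bsf_from_spectra(phi_air, phi_scatter)


# --- depth dose and profiles ------------------------------------------------

@dataclass
class DepthCurve:
    """Central-axis depth dose, normalized to 100% at the surface."""

    depths_mm: np.ndarray
    values: np.ndarray  # percent
    normalization: str = "surface"

    def __post_init__(self):
        self.depths_mm = np.asarray(self.depths_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.normalization == "surface" and \
                not np.isclose(self.values[0], 100.0):
            raise ValueError("surface-normalized PDD must start at 100%")

    def at(self, depth_mm: float) -> float:
        return float(np.interp(depth_mm, self.depths_mm, self.values))


@dataclass
class Profile:
    """Lateral dose profile at a depth, area-normalized in the 80% width.

    The field width is the distance between the 50%-of-central-value points;
    the normalization region is the central 80% of that width, and values
    are divided by the trapezoidal mean over the region.
    """

    offsets_mm: np.ndarray
    values: np.ndarray
    depth_mm: float
    axis: str = "cross-plane"
    norm_constant: float = 1.0


def extract_pdd(dose: DoseGrid, axis: tuple[int, int] | None = None) -> DepthCurve:
    """Percentage depth dose along z through the beam axis column."""
    nx, ny, nz = dose.shape
    i, j = axis if axis is not None else (nx // 2, ny // 2)
    col = dose.dose[i, j, :]
    if col[0] <= 0:
        raise ValueError("zero surface dose on the selected axis")
    dz = dose.voxel_size[2]
    depths = (np.arange(nz) + 0.5) * dz
    depths = depths - depths[0]  # surface bin at depth 0
    return DepthCurve(depths, 100.0 * col / col[0])


def extract_profile(dose: DoseGrid, depth_mm: float, axis: str = "cross-plane",
                    other_index: int | None = None) -> Profile:
    """Lateral profile at a depth, normalized per the 80%-width convention."""
    nx, ny, nz = dose.shape
    k = min(int(depth_mm / dose.voxel_size[2]), nz - 1)
    if axis == "cross-plane":
        j = other_index if other_index is not None else ny // 2
        values = dose.dose[:, j, k].astype(float)
        pitch, n, o = dose.voxel_size[0], nx, dose.origin[0]
    elif axis == "in-plane":
        i = other_index if other_index is not None else nx // 2
        values = dose.dose[i, :, k].astype(float)
        pitch, n, o = dose.voxel_size[1], ny, dose.origin[1]
    else:
        raise ValueError("axis must be 'cross-plane' or 'in-plane'")
    offsets = o + (np.arange(n) + 0.5) * pitch

    center = values[n // 2]
    if center <= 0:
        raise ValueError("zero central value at requested depth")
    half = 0.5 * center
    above = values >= half
    idx = np.nonzero(above)[0]
    left, right = offsets[idx[0]], offsets[idx[-1]]
    width = right - left
    mid = 0.5 * (left + right)
    region = (offsets >= mid - 0.4 * width) & (offsets <= mid + 0.4 * width)
    if region.sum() < 2:
        region = above
    mean = np.trapezoid(values[region], offsets[region]) / \
        (offsets[region][-1] - offsets[region][0])
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError("profile normalization constant not positive")
    return Profile(offsets, values / mean, depth_mm, axis, float(mean))


def output_factor(dose: DoseGrid, reference: DoseGrid,
                  aperture_area_cm2: float | None = None,
                  reference_area_cm2: float | None = None) -> float:
    """Ratio of central-axis surface dose to that of the reference field.

    Doses are per source particle; the analytic source spreads its particles
    uniformly over the open aperture, so comparing different apertures at a
    fixed tube output requires scaling each dose by its aperture area
    (constant exit-plane fluence).  Pass both areas to apply that scaling;
    leave them unset when the two runs share one source geometry.
    """
    d = dose.central_axis_profile()[0]
    r = reference.central_axis_profile()[0]
    if r <= 0:
        raise ValueError("reference surface dose is zero")
    if (aperture_area_cm2 is None) != (reference_area_cm2 is None):
        raise ValueError("provide both aperture areas or neither")
    if aperture_area_cm2 is not None:
        d = d * aperture_area_cm2
        r = r * reference_area_cm2
    return float(d / r)


# --- absolute dose and calibration ------------------------------------------

def absolute_dose(d_phantom: DoseGrid, d_sim_water_surface: float,
                  output_gy_per_mu: float, mu: float) -> DoseGrid:
    """Absolute dose grid: ``D = D_phantom / D_water_surface * O * MU``.

    `d_sim_water_surface` is the central surface-voxel dose (Gy/particle) of
    the matching watertank run; `output_gy_per_mu` is the unit output for
    the applicator.  Dose-to-medium semantics of the input are preserved.
    """
    if d_sim_water_surface <= 0:
        raise ValueError("water surface dose must be positive")
    if output_gy_per_mu <= 0 or mu <= 0:
        raise ValueError("output and MU must be positive")
    return d_phantom.scaled(output_gy_per_mu * mu / d_sim_water_surface)


def calibration_coefficient(d_w_mc: float, m_w: float,
                            muen_water_air: float) -> float:
    """Dose-to-water calibration coefficient N_dw (Gy/nC).

    ``N_dw = D_w^MC / (M_w * muen_ratio)`` -- the Monte Carlo dose in the
    water compartment divided by the product of the chamber charge reading
    and the spectrum-weighted water/air mass energy-absorption ratio.
    """
    if d_w_mc <= 0 or m_w <= 0 or muen_water_air <= 0:
        raise ValueError("calibration inputs must be positive")
    return d_w_mc / (m_w * muen_water_air)


def dose_to_medium_from_reading(n_dw: float, reading_nc: float,
                                muen_med_air: float) -> float:
    """Measured dose-to-medium: ``D_med = N_dw * M * muen_med_air``."""
    return n_dw * reading_nc * muen_med_air


def percent_difference(reference: float, test: float) -> float:
    """Signed percent difference ``(ref - test) / ref * 100``."""
    if reference == 0:
        raise ValueError("zero reference value")
    return (reference - test) / reference * 100.0


def spectrum_weighted_muen_ratio(spectrum: Spectrum, medium: str,
                                 reference: str = "air") -> float:
    """Kerma-weighted mean muen/rho ratio medium-to-reference over a spectrum."""
    mid = spectrum.midpoints
    populated = spectrum.fluence > 0
    e = mid[populated]
    phi = spectrum.fluence[populated]
    muen_ref = xsdata.get_table(reference).muen(e)
    muen_med = xsdata.mass_energy_absorption(medium, e)
    w = phi * e * spectrum.widths[populated]
    ref_kerma = np.sum(w * muen_ref)
    if ref_kerma <= 0:
        raise ValueError("empty spectrum")
    return float(np.sum(w * muen_med) / ref_kerma)


# --- gamma index ------------------------------------------------------------

@dataclass
class GammaResult:
    gamma: np.ndarray          # NaN below threshold
    pass_fraction: float       # percent of evaluated points with gamma <= 1
    dose_crit_percent: float
    dist_crit_mm: float
    threshold_percent: float

    def __post_init__(self):
        vals = self.gamma[np.isfinite(self.gamma)]
        if np.any(vals < 0):
            raise ValueError("gamma must be non-negative")
        if not 0.0 <= self.pass_fraction <= 100.0:
            raise ValueError("pass fraction out of [0, 100]")


def gamma_index(reference: np.ndarray, evaluated: np.ndarray,
                pitch_mm, dose_crit_percent: float = 3.0,
                dist_crit_mm: float = 2.0,
                threshold_percent: float = 20.0,
                refine: int = 4) -> GammaResult:
    """Global-normalization gamma analysis of two registered dose grids.

    For each reference point above ``threshold_percent`` of the reference
    maximum, gamma is the minimum over evaluated points (on a grid refined
    `refine`-fold by linear interpolation, searched within 3 distance
    criteria) of ``sqrt((dD / (crit% * max_ref))^2 + (dr / dist_crit)^2)``.
    The dose criterion is global: a fixed fraction of the reference maximum.
    Note gamma is not symmetric under swapping reference and evaluated
    distributions; the reference defines both threshold and normalization.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("dose grids must be registered (same shape)")
    if ref.ndim not in (2, 3):
        raise ValueError("gamma supports 2D and 3D grids")
    if dose_crit_percent <= 0 or dist_crit_mm <= 0:
        raise ValueError("criteria must be positive")
    pitch = np.broadcast_to(np.asarray(pitch_mm, dtype=float), (ref.ndim,))
    max_ref = ref.max()
    if max_ref <= 0:
        raise ValueError("reference maximum must be positive")
    dose_tol = dose_crit_percent / 100.0 * max_ref
    eval_mask = ref >= threshold_percent / 100.0 * max_ref
    if not np.any(eval_mask):
        raise ValueError("all reference points below the dose threshold")

    # refined evaluated grid
    axes = [np.arange(n) * p for n, p in zip(ref.shape, pitch)]
    interp = RegularGridInterpolator(axes, ev, bounds_error=False,
                                     fill_value=None)
    search = 3.0 * dist_crit_mm
    offsets_1d = [np.arange(-search, search + 1e-9, p / refine)
                  for p in pitch]
    mesh = np.meshgrid(*offsets_1d, indexing="ij")
    disp = np.stack([m.ravel() for m in mesh], axis=1)
    r2 = np.sum(disp**2, axis=1)
    keep = r2 <= search**2
    disp, r2 = disp[keep], r2[keep]
    dist_term = r2 / dist_crit_mm**2

    gamma = np.full(ref.shape, np.nan)
    pts = np.argwhere(eval_mask)
    coords = pts * pitch
    # process in chunks to bound memory
    chunk = max(1, int(2e7 // len(disp)))
    for start in range(0, len(pts), chunk):
        sel = slice(start, start + chunk)
        sample = coords[sel][:, None, :] + disp[None, :, :]
        ev_vals = interp(sample.reshape(-1, ref.ndim)).reshape(
            sample.shape[:2])
        dd = (ev_vals - ref[eval_mask][sel][:, None]) / dose_tol
        g2 = dd**2 + dist_term[None, :]
        gamma[tuple(pts[sel].T)] = np.sqrt(g2.min(axis=1))

    vals = gamma[eval_mask]
    pass_fraction = 100.0 * np.count_nonzero(vals <= 1.0) / len(vals)
    return GammaResult(gamma, float(pass_fraction), dose_crit_percent,
                       dist_crit_mm, threshold_percent)


# --- DVH --------------------------------------------------------------------

def dvh(dose: DoseGrid | np.ndarray, mask: StructureMask | None = None,
        n_bins: int = 200):
    """Cumulative dose-volume histogram for a structure.

    Returns (dose_levels, volume_percent): the percentage of the structure
    volume receiving at least each dose level.  V(0) = 100% and the curve is
    monotone non-increasing.
    """
    values = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    if mask is not None:
        if mask.values.shape != values.shape:
            raise ValueError("mask shape mismatch")
        values = values[mask.values]
    values = values.ravel()
    if values.size == 0:
        raise ValueError("empty structure")
    top = values.max()
    levels = np.linspace(0.0, top * 1.001 if top > 0 else 1.0, n_bins)
    volume = np.array([np.count_nonzero(values >= lv) for lv in levels],
                      dtype=float) / values.size * 100.0
    return levels, volume
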