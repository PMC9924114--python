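"""Beam setup: applicator catalogue, cutout apertures, and the source model.

The treatment unit is described by an applicator (energy, SSD, aperture) and
a beam placement in the spherical-polar convention used by voxel Monte Carlo
dose codes: ``theta`` is the polar angle of the beam direction from the +z
axis, ``phi`` its azimuth from +x, and ``phicol`` the collimator rotation
about the beam axis.  The default co-planar beam (theta=0, phi=0) points down
+z into the phantom.

The source model is an analytic point source at the focal spot: particle
positions are sampled uniformly over the open part of the exit-window
aperture, directions diverge from the focal spot through the sampled
position, and energies follow the discrete spectrum distribution.  A
phase-space-like text reader is provided for externally generated sources.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, box

from .phantom import StructureMask
from .spectrum import Spectrum

__all__ = [
    "Applicator",
    "BeamSetup",
    "catalogue",
    "get_applicator",
    "cutout_polygon",
    "cutout_mask",
    "sample_source_particles",
    "read_phsp",
    "write_phsp",
]


@dataclass(frozen=True)
class Applicator:
    """A clinical applicator: energy, SSD, and aperture at the exit window."""

    id: str
    kvp: float
    ssd_cm: float
    aperture: tuple  # ("circle", diameter_cm) | ("rectangle", w_cm, h_cm)
    end_type: str = "open"
    reference: bool = False
    placeholder: bool = False

    def __post_init__(self):
        if not 20.0 <= self.ssd_cm <= 50.0:
            raise ValueError(f"{self.id}: SSD {self.ssd_cm} outside 20-50 cm")
        kind = self.aperture[0]
        if kind == "circle":
            d = self.aperture[1]
            if not 2.0 <= d <= 20.0:
                raise ValueError(f"{self.id}: circle diameter {d} cm out of range")
        elif kind == "rectangle":
            w, h = self.aperture[1], self.aperture[2]
            if not (2.0 <= w <= 20.0 and 2.0 <= h <= 20.0):
                raise ValueError(f"{self.id}: rectangle {w}x{h} cm out of range")
        else:
            raise ValueError(f"{self.id}: unknown aperture kind {kind!r}")

    def aperture_polygon(self, n_circle: int = 128) -> Polygon:
        if self.aperture[0] == "circle":
            return Point(0.0, 0.0).buffer(self.aperture[1] / 2.0,
                                          quad_segs=n_circle // 4)
        w, h = self.aperture[1], self.aperture[2]
        return box(-w / 2.0, -h / 2.0, w / 2.0, h / 2.0)

    def area_cm2(self) -> float:
        if self.aperture[0] == "circle":
            return math.pi * (self.aperture[1] / 2.0) ** 2
        return self.aperture[1] * self.aperture[2]


# Reference applicators: 10 cm circle at 30 cm SSD for 70/100/125 kV and
# 10x10 cm^2 at 50 cm SSD for 200 kV.  The remaining lettered entries fill
# out the clinical set of 49 energy-applicator combinations; their physical
# dimensions are site commissioning data, so they are shipped as editable
# placeholders with plausible sizes increasing through the alphabet.
_LOW_KV_SIZES = {  # letter -> aperture for the 70/100/125 kV applicators
    "A": ("circle", 2.0), "B": ("circle", 3.0), "C": ("circle", 4.0),
    "D": ("circle", 5.0), "E": ("circle", 6.0), "F": ("circle", 8.0),
    "G": ("circle", 9.0), "H": ("circle", 10.0),
    "I": ("rectangle", 4.0, 4.0), "J": ("rectangle", 5.0, 5.0),
    "K": ("rectangle", 8.0, 8.0), "L": ("rectangle", 10.0, 10.0),
}
_HIGH_KV_SIZES = {  # letter -> aperture for the 200 kV applicators
    "M": ("circle", 5.0), "N": ("circle", 7.0), "O": ("circle", 9.0),
    "P": ("circle", 10.0), "Q": ("rectangle", 6.0, 6.0),
    "R": ("rectangle", 8.0, 8.0), "S": ("rectangle", 10.0, 10.0),
    "T": ("rectangle", 12.0, 12.0), "U": ("rectangle", 10.0, 15.0),
    "V": ("rectangle", 15.0, 10.0), "W": ("rectangle", 15.0, 15.0),
    "X": ("rectangle", 12.0, 18.0), "Y": ("rectangle", 20.0, 20.0),
}


def catalogue() -> list[Applicator]:
    """The clinical registry of 49 energy-applicator combinations."""
    apps = []
    for kvp in (70.0, 100.0, 125.0):
        for letter, aperture in _LOW_KV_SIZES.items():
            ref = (letter == "H")  # 10 cm circle at 30 cm SSD
            apps.append(Applicator(
                id=f"{kvp:g}{letter}", kvp=kvp, ssd_cm=30.0,
                aperture=aperture, reference=ref, placeholder=not ref))
    for letter, aperture in _HIGH_KV_SIZES.items():
        ref = (letter == "S")  # 10x10 at 50 cm SSD
        apps.append(Applicator(
            id=f"200{letter}", kvp=200.0, ssd_cm=50.0,
            aperture=aperture, reference=ref, placeholder=not ref))
    return apps


def get_applicator(app_id: str) -> Applicator:
    for app in catalogue():
        if app.id == app_id:
            return app
    raise KeyError(f"unknown applicator id {app_id!r}")


def reference_applicator(kvp: float) -> Applicator:
    for app in catalogue():
        if app.reference and app.kvp == kvp:
            return app
    raise KeyError(f"no reference applicator for {kvp} kV")


@dataclass
class BeamSetup:
    """Beam placement: exit-window centre, direction angles, and cutout.

    `exit_window_center` is in phantom coordinates (cm); the focal spot sits
    `applicator.ssd_cm` upstream along the beam axis.  `cutout` is an
    optional simple polygon (cm, exit-window frame) restricting the aperture.
    """

    applicator: Applicator
    exit_window_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    theta: float = 0.0   # polar angle of beam direction from +z, degrees
    phi: float = 0.0     # azimuth from +x, degrees
    phicol: float = 0.0  # collimator rotation about the beam axis, degrees
    cutout: Polygon | None = None

    def __post_init__(self):
        if self.cutout is not None:
            if not self.cutout.is_simple or self.cutout.area <= 0:
                raise ValueError("cutout polygon must be simple with area > 0")
            aperture = self.applicator.aperture_polygon()
            if not aperture.buffer(1e-6).contains(self.cutout):
                raise ValueError("cutout must lie inside the aperture")

    def direction(self) -> np.ndarray:
        """Unit beam-axis direction from (theta, phi)."""
        th, ph = math.radians(self.theta), math.radians(self.phi)
        return np.array([math.sin(th) * math.cos(ph),
                         math.sin(th) * math.sin(ph),
                         math.cos(th)])

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, v, w): in-plane axes of the exit window plus the beam axis.

        The collimator angle `phicol` rotates (u, v) about w.
        """
        w = self.direction()
        helper = np.array([0.0, 1.0, 0.0]) if abs(w[2]) > 0.9 \
            else np.array([0.0, 0.0, 1.0])
        u = np.cross(helper, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        c, s = math.cos(math.radians(self.phicol)), math.sin(math.radians(self.phicol))
        return c * u + s * v, -s * u + c * v, w

    def focal_spot(self) -> np.ndarray:
        return np.asarray(self.exit_window_center) - \
            self.applicator.ssd_cm * self.direction()

    def open_region(self) -> Polygon:
        aperture = self.applicator.aperture_polygon()
        if self.cutout is None:
            return aperture
        return aperture.intersection(self.cutout)


# --- cutout shapes ----------------------------------------------------------

def cutout_polygon(shape: str, size_cm: float = 6.0) -> Polygon:
    """Built-in test cutout shapes: 'C', 'L', and '8' (figure-eight).

    The shapes are challenging apertures used for end-to-end testing: 'C'
    and 'L' are concave, '8' has two separate holes.  `size_cm` is the
    bounding size.
    """
    s = size_cm
    t = s / 3.0
    if shape == "C":
        outer = box(-s / 2, -s / 2, s / 2, s / 2)
        notch = box(-s / 2 + t, -s / 2 + t, s / 2 + 0.01, s / 2 - t)
        return outer.difference(notch)
    if shape == "L":
        vertical = box(-s / 2, -s / 2, -s / 2 + t, s / 2)
        horizontal = box(-s / 2, -s / 2, s / 2, -s / 2 + t)
        return vertical.union(horizontal)
    if shape == "8":
        r_out = s / 4.0
        r_in = r_out / 2.0
        top = Point(0, s / 4).buffer(r_out).difference(
            Point(0, s / 4).buffer(r_in))
        bottom = Point(0, -s / 4).buffer(r_out).difference(
            Point(0, -s / 4).buffer(r_in))
        return top.union(bottom)
    raise ValueError(f"unknown cutout shape {shape!r}")


def cutout_mask(polygon: Polygon, x_edges, y_edges,
                name: str = "cutout") -> StructureMask:
    """Rasterize an aperture polygon onto a 2D grid of voxel centres.

    Voxel centres inside the polygon are open (True); the mask is 2D with
    shape (len(x_edges)-1, len(y_edges)-1).
    """
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("degenerate cutout polygon (zero area)")
    xc = 0.5 * (np.asarray(x_edges)[:-1] + np.asarray(x_edges)[1:])
    yc = 0.5 * (np.asarray(y_edges)[:-1] + np.asarray(y_edges)[1:])
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    from shapely import contains_xy
    open_mask = contains_xy(polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
    return StructureMask(open_mask, name)


# --- source sampling --------------------------------------------------------

def _sample_in_polygon(poly: Polygon, n: int, rng: np.random.Generator):
    """Uniform points in a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = poly.bounds
    from shapely import contains_xy
    xs = np.empty(n)
    ys = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 128)
        px = rng.uniform(minx, maxx, m)
        py = rng.uniform(miny, maxy, m)
        ok = contains_xy(poly, px, py)
        take = min(int(ok.sum()), n - filled)
        xs[filled:filled + take] = px[ok][:take]
        ys[filled:filled + take] = py[ok][:take]
        filled += take
    return xs, ys


def sample_source_particles(beam: BeamSetup, spectrum: Spectrum, n: int,
                            rng: np.random.Generator):
    """Sample `n` source photons at the applicator exit window.

    Returns (positions cm, unit directions, energies keV, weights).
    Positions are uniform over the open aperture region; directions diverge
    from the focal spot; energies follow the spectrum's discrete
    distribution (bin midpoints).
    """
    region = beam.open_region()
    if region.is_empty or region.area <= 0:
        raise ValueError("cutout blocks the entire aperture")
    u, v, w = beam.basis()
    xs, ys = _sample_in_polygon(region, n, rng)
    center = np.asarray(beam.exit_window_center, dtype=float)
    pos = center + xs[:, None] * u + ys[:, None] * v
    focal = beam.focal_spot()
    dirs = pos - focal
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]

    tot = spectrum.fluence.sum()
    if tot <= 0:
        raise ValueError("spectrum has zero fluence")
    probs = spectrum.fluence / tot
    energies = rng.choice(spectrum.midpoints, size=n, p=probs)
    weights = np.ones(n)
    return pos, dirs, energies, weights


# --- phase-space text I/O ---------------------------------------------------

def write_phsp(path, energies, positions, directions, weights) -> None:
    """One particle per line: ``E_keV x y z u v w weight`` (cm)."""
    with open(path, "w") as fh:
        fh.write("# E_keV x y z u v w weight\n")
        for e, p, d, wt in zip(energies, positions, directions, weights):
            fh.write(f"{e:.6g} {p[0]:.6g} {p[1]:.6g} {p[2]:.6g} "
                     f"{d[0]:.8g} {d[1]:.8g} {d[2]:.8g} {wt:.6g}\n")


def read_phsp(path):
    """Read the phase-space text format; returns (E, pos, dirs, weights)."""
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] != 8:
        raise ValueError(f"{path}: expected 8 columns, got {arr.shape[1]}")
    dirs = arr[:, 4:7]
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError(f"{path}: direction vectors not normalized")
    return arr[:, 0], arr[:, 1:4], dirs, arr[:, 7]
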