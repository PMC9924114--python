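"""Voxel phantoms: HU grids, tissue segmentation, density mapping, and I/O.

A CT-style HU grid is segmented into a :class:`VoxelPhantom` (per-voxel
material index and mass density) using an anatomical-site segmentation scheme
(ordered, half-open HU intervals that partition the full HU range) and a
piecewise-linear HU-to-density calibration curve.  Air and heavy metals
(lead, gold) always take their nominal densities rather than curve values.
Structure masks allow HU overwrite, which is how lead cutouts and internal
shields enter a simulation phantom.

The phantom text format is an egsphant-style layout: a header with the
material list and voxel boundaries followed by material-index characters and
density blocks, documented in ``docs/methods.md``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import xsdata

__all__ = [
    "HUGrid",
    "SegmentationScheme",
    "DensityCurve",
    "VoxelPhantom",
    "StructureMask",
    "default_scheme",
    "default_density_curve",
    "segment",
    "overwrite_structure",
    "crop",
    "make_watertank",
    "make_three_compartment",
    "write_phantom",
    "read_phantom",
]

HU_MIN, HU_MAX = -1024, 40000  # supported HU range (metals live at the top)


@dataclass
class HUGrid:
    """3D array of Hounsfield units on a regular grid.

    Axis order is (x, y, z); `voxel_size` and `origin` are in mm, with the
    origin at the lower corner of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("HU grid must be a non-empty 3D array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive on all axes")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class StructureMask:
    """Boolean voxel mask naming a structure on its parent grid."""

    values: np.ndarray
    name: str = "structure"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)


@dataclass
class SegmentationScheme:
    """Ordered (tissue name, [lo, hi) HU interval, material) entries.

    The intervals must be disjoint, contiguous, and jointly cover the full
    supported HU range; the first entry is air and the last entries are the
    heavy metals.  Boundary HU values belong to the higher interval.
    """

    group_name: str
    entries: list[tuple[str, tuple[int, int], str]]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("scheme needs at least one entry")
        lo0 = self.entries[0][1][0]
        hi_prev = lo0
        for name, (lo, hi), mat in self.entries:
            if lo != hi_prev or hi <= lo:
                raise ValueError(
                    f"scheme {self.group_name!r}: intervals must be "
                    f"contiguous half-open [lo, hi); bad entry {name!r}")
            hi_prev = hi
            xsdata.get_material(mat)  # validate material exists
        if lo0 > HU_MIN or hi_prev < HU_MAX:
            raise ValueError(
                f"scheme must cover [{HU_MIN}, {HU_MAX}); got [{lo0}, {hi_prev})")

    @property
    def breakpoints(self) -> np.ndarray:
        return np.array([lo for _, (lo, _), _ in self.entries[1:]])

    @property
    def materials(self) -> list[str]:
        return [mat for _, _, mat in self.entries]

    @classmethod
    def from_yaml(cls, path) -> "SegmentationScheme":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = [(e["tissue"], (int(e["lo"]), int(e["hi"])), e["material"])
                   for e in doc["entries"]]
        return cls(doc["group"], entries)


# Default schemes for the three anatomical groups.  The breakpoints are
# literature-typical commissioning values, editable per site; they are not a
# universal calibration.
_DEFAULT_SCHEMES = {
    "head-neck": [
        ("air", (HU_MIN, -950), "air"),
        ("lung", (-950, -200), "lung"),
        ("adipose", (-200, -50), "adipose"),
        ("soft tissue", (-50, 120), "soft_tissue"),
        ("trabecular bone", (120, 700), "bone_trabecular"),
        ("cortical bone", (700, 2900), "bone_cortical"),
        ("gold", (2900, 20000), "Au"),
        ("lead", (20000, HU_MAX), "Pb"),
    ],
    "torso": [
        ("air", (HU_MIN, -950), "air"),
        ("lung", (-950, -150), "lung"),
        ("adipose", (-150, -20), "adipose"),
        ("muscle", (-20, 150), "muscle"),
        ("trabecular bone", (150, 800), "bone_trabecular"),
        ("cortical bone", (800, 2900), "bone_cortical"),
        ("gold", (2900, 20000), "Au"),
        ("lead", (20000, HU_MAX), "Pb"),
    ],
    "extremity": [
        ("air", (HU_MIN, -950), "air"),
        ("adipose", (-950, -30), "adipose"),
        ("muscle", (-30, 200), "muscle"),
        ("trabecular bone", (200, 900), "bone_trabecular"),
        ("cortical bone", (900, 2900), "bone_cortical"),
        ("gold", (2900, 20000), "Au"),
        ("lead", (20000, HU_MAX), "Pb"),
    ],
}


def default_scheme(group: str = "torso") -> SegmentationScheme:
    """Shipped segmentation scheme for an anatomical group."""
    try:
        entries = _DEFAULT_SCHEMES[group]
    except KeyError:
        raise KeyError(f"unknown group {group!r}; have {sorted(_DEFAULT_SCHEMES)}")
    return SegmentationScheme(group, list(entries))


@dataclass
class DensityCurve:
    """Piecewise-linear HU -> mass density (g/cm^3), clamped at the ends."""

    hu: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("control points must be strictly increasing in HU")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")
        if np.any(np.diff(self.density) < 0):
            raise ValueError("density curve must be monotone non-decreasing")

    def __call__(self, hu):
        return np.interp(hu, self.hu, self.density)

    @classmethod
    def from_csv(cls, path) -> "DensityCurve":
        arr = np.loadtxt(path, delimiter=",", comments="#")
        return cls(arr[:, 0], arr[:, 1])


def default_density_curve() -> DensityCurve:
    """Generic CT density calibration: air, water, and a cortical-bone point."""
    return DensityCurve([-1000.0, 0.0, 1500.0], [0.001, 1.000, 1.92])


@dataclass
class VoxelPhantom:
    """Segmented phantom: material index + density per voxel, plus geometry."""

    material_index: np.ndarray  # int per voxel, indexing `materials`
    density: np.ndarray         # g/cm^3 per voxel
    materials: list[str]
    grid: HUGrid                # geometry carrier (values may be HU or zeros)

    def __post_init__(self):
        if self.material_index.shape != self.density.shape:
            raise ValueError("index/density shape mismatch")
        if self.material_index.max(initial=0) >= len(self.materials):
            raise ValueError("material index out of range")
        if np.any(self.density <= 0):
            raise ValueError("densities must be positive")

    @property
    def shape(self):
        return self.material_index.shape

    @property
    def voxel_size(self):
        return self.grid.voxel_size

    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz / 1000.0

    def total_mass_g(self) -> float:
        return float(self.density.sum() * self.voxel_volume_cm3())


def segment(hu: HUGrid, scheme: SegmentationScheme | None = None,
            curve: DensityCurve | None = None) -> VoxelPhantom:
    """Segment a HU grid into materials and densities.

    Each voxel gets the unique scheme interval containing its HU; density
    comes from the calibration curve except for fixed-density materials
    (air, lead, gold), which use their nominal densities.  HU outside the
    supported range are clamped (the clamp count is recorded on the result
    as ``n_clamped``).
    """
    scheme = scheme or default_scheme()
    curve = curve or default_density_curve()
    values = np.asarray(hu.values)
    n_clamped = int(np.count_nonzero((values < HU_MIN) | (values >= HU_MAX)))
    clamped = np.clip(values, HU_MIN, HU_MAX - 1)

    idx = np.searchsorted(scheme.breakpoints, clamped, side="right")
    materials = scheme.materials
    density = curve(clamped).astype(float)
    for i, mat_name in enumerate(materials):
        mat = xsdata.get_material(mat_name)
        if mat.fixed_density:
            density[idx == i] = mat.nominal_density
    density = np.maximum(density, 1e-4)
    out = VoxelPhantom(idx.astype(np.int8), density, list(materials), hu)
    out.n_clamped = n_clamped
    return out


def overwrite_structure(hu: HUGrid, mask: StructureMask, new_hu: int) -> HUGrid:
    """Return a new HU grid with `new_hu` inside the mask; input untouched."""
    if mask.values.shape != hu.shape:
        raise ValueError(
            f"mask shape {mask.values.shape} != grid shape {hu.shape}")
    values = hu.values.copy()
    values[mask.values] = new_hu
    return HUGrid(values, hu.voxel_size, hu.origin)


def crop(hu: HUGrid, bounds) -> HUGrid:
    """Crop to voxel-index ranges ((i0,i1),(j0,j1),(k0,k1)), end exclusive."""
    (i0, i1), (j0, j1), (k0, k1) = bounds
    nx, ny, nz = hu.shape
    if not (0 <= i0 < i1 <= nx and 0 <= j0 < j1 <= ny and 0 <= k0 < k1 <= nz):
        raise ValueError(f"crop bounds {bounds} invalid for shape {hu.shape}")
    sub = hu.values[i0:i1, j0:j1, k0:k1]
    origin = tuple(o + lo * v for o, lo, v in
                   zip(hu.origin, (i0, j0, k0), hu.voxel_size))
    return HUGrid(sub.copy(), hu.voxel_size, origin)


def make_watertank(size_cm=(40.0, 40.0, 30.0), voxel_mm=(2.0, 2.0, 2.0),
                   center_xy: bool = True) -> VoxelPhantom:
    """Homogeneous water tank, default 40x40x30 cm at 2 mm voxels.

    With `center_xy` the x/y origin is shifted so the beam axis (x=y=0)
    passes through the tank centre; z runs from 0 (surface) downward.
    """
    shape = tuple(int(round(s * 10.0 / v)) for s, v in zip(size_cm, voxel_mm))
    origin = (-shape[0] * voxel_mm[0] / 2.0, -shape[1] * voxel_mm[1] / 2.0, 0.0) \
        if center_xy else (0.0, 0.0, 0.0)
    grid = HUGrid(np.zeros(shape, dtype=np.int16), tuple(voxel_mm), origin)
    idx = np.zeros(shape, dtype=np.int8)
    density = np.full(shape, 1.0)
    return VoxelPhantom(idx, density, ["water"], grid)


def make_three_compartment(materials=("water", "adipose", "muscle"),
                           size_cm=(12.0, 12.0, 12.0),
                           compartment_depth_cm=(2.0, 8.0),
                           voxel_mm=(2.0, 2.0, 2.0)):
    """Water tank with three lateral compartments of the given materials.

    The compartments are side-by-side slabs spanning the x axis between the
    stated depths, surrounded by water.  Returns (phantom, centers) where
    `centers` maps material name to the compartment centre in cm, for
    point-dose extraction.
    """
    if len(materials) != 3:
        raise ValueError("need exactly three compartment materials")
    tank = make_watertank(size_cm, voxel_mm)
    shape = tank.shape
    mats = ["water"] + [m for m in materials if m != "water"]
    idx = np.zeros(shape, dtype=np.int8)
    density = np.full(shape, 1.0)
    dx, dy, dz = (v / 10.0 for v in voxel_mm)  # cm
    x0, y0, _ = (o / 10.0 for o in tank.grid.origin)
    k0 = int(round(compartment_depth_cm[0] / dz))
    k1 = int(round(compartment_depth_cm[1] / dz))
    centers = {}
    width = shape[0] // 3
    for c, mat_name in enumerate(materials):
        i0, i1 = c * width, (c + 1) * width if c < 2 else shape[0]
        mat = xsdata.get_material(mat_name)
        m_idx = mats.index(mat_name) if mat_name in mats else None
        idx[i0:i1, :, k0:k1] = m_idx
        density[i0:i1, :, k0:k1] = mat.nominal_density
        centers[mat_name] = (
            x0 + (i0 + i1) / 2.0 * dx,
            y0 + shape[1] / 2.0 * dy,
            (k0 + k1) / 2.0 * dz,
        )
    phantom = VoxelPhantom(idx, density, mats, tank.grid)
    return phantom, centers


# --- egsphant-style text I/O ------------------------------------------------

_INDEX_CHARS = "123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def write_phantom(phantom: VoxelPhantom, path) -> None:
    """Write the egsphant-style text layout (see docs for the format)."""
    nx, ny, nz = phantom.shape
    buf = io.StringIO()
    buf.write(f"{len(phantom.materials)}\n")
    for m in phantom.materials:
        buf.write(f"{m}\n")
    buf.write(f"{nx} {ny} {nz}\n")
    for axis in range(3):
        o = phantom.grid.origin[axis] / 10.0
        v = phantom.voxel_size[axis] / 10.0
        n = phantom.shape[axis]
        bounds = o + v * np.arange(n + 1)
        buf.write(" ".join(f"{b:.6g}" for b in bounds) + "\n")
    for k in range(nz):
        for j in range(ny):
            row = phantom.material_index[:, j, k]
            buf.write("".join(_INDEX_CHARS[i] for i in row) + "\n")
        buf.write("\n")
    for k in range(nz):
        for j in range(ny):
            buf.write(" ".join(f"{d:.6g}" for d in phantom.density[:, j, k])
                      + "\n")
        buf.write("\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_phantom(path) -> VoxelPhantom:
    """Read the egsphant-style text layout written by :func:`write_phantom`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0

    def next_line():
        nonlocal pos
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            raise ValueError(f"{path}: truncated file at line {pos + 1}")
        pos += 1
        return lines[pos - 1]

    try:
        n_mat = int(next_line())
    except ValueError as exc:
        raise ValueError(f"{path}: bad material count at line {pos}") from exc
    materials = [next_line().strip() for _ in range(n_mat)]
    try:
        nx, ny, nz = (int(x) for x in next_line().split())
    except ValueError as exc:
        raise ValueError(f"{path}: bad shape line at line {pos}") from exc
    bounds = []
    for n in (nx, ny, nz):
        vals = [float(x) for x in next_line().split()]
        if len(vals) != n + 1:
            raise ValueError(f"{path}: boundary list length mismatch "
                             f"at line {pos}")
        bounds.append(np.asarray(vals))
    voxel = tuple(float((b[1] - b[0]) * 10.0) for b in bounds)
    origin = tuple(float(b[0] * 10.0) for b in bounds)
    idx = np.zeros((nx, ny, nz), dtype=np.int8)
    for k in range(nz):
        for j in range(ny):
            row = next_line().strip()
            if len(row) != nx:
                raise ValueError(f"{path}: index row length {len(row)} != {nx}"
                                 f" at line {pos}")
            idx[:, j, k] = [_INDEX_CHARS.index(c) for c in row]
    density = np.zeros((nx, ny, nz))
    for k in range(nz):
        for j in range(ny):
            vals = [float(x) for x in next_line().split()]
            if len(vals) != nx:
                raise ValueError(f"{path}: density row length mismatch "
                                 f"at line {pos}")
            density[:, j, k] = vals
    grid = HUGrid(np.zeros((nx, ny, nz), dtype=np.int16), voxel, origin)
    return VoxelPhantom(idx, density, materials, grid)
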