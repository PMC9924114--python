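"""Materials and photon interaction coefficient tables.

Every physics computation in kvplan (spectrum filtration, air kerma, HVL,
backscatter factors, and the Monte Carlo transport engine) draws its cross
sections from here.  The data are vendored plain-text tables of mass
attenuation (``mu/rho``, with and without the coherent contribution) and mass
energy-absorption (``muen/rho``) coefficients on a common energy grid covering
10--500 keV, interpolated log-log between knots.  Mixtures without a vendored
table are built by elemental additivity: ``mu/rho = sum_i w_i (mu/rho)_i``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "Material",
    "CoefficientTable",
    "get_material",
    "get_table",
    "list_materials",
    "mass_attenuation",
    "mass_energy_absorption",
    "electrons_per_gram",
    "mixture_table",
]

# Standard atomic weights for the elements appearing in the registry.
ATOMIC_WEIGHTS = {
    1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 11: 22.990, 12: 24.305,
    13: 26.982, 15: 30.974, 16: 32.06, 17: 35.45, 18: 39.948, 19: 39.098,
    20: 40.078, 26: 55.845, 29: 63.546, 50: 118.71, 74: 183.84,
    79: 196.967, 82: 207.2,
}

ELEMENT_SYMBOLS = {1: "H", 6: "C", 7: "N", 8: "O", 13: "Al", 29: "Cu",
                   50: "Sn", 74: "W", 79: "Au", 82: "Pb"}

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class Material:
    """A named material: elemental composition by mass and nominal density."""

    name: str
    composition: tuple[tuple[int, float], ...]  # (Z, mass fraction)
    nominal_density: float  # g/cm^3
    table_name: str | None = None
    fixed_density: bool = False

    def __post_init__(self):
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, not 1")
        if self.nominal_density <= 0:
            raise ValueError(f"non-positive density for {self.name!r}")


@dataclass
class CoefficientTable:
    """Photon coefficients vs energy for one material, log-log interpolated.

    ``mu_over_rho`` is the total mass attenuation coefficient including
    coherent scattering; ``mu_over_rho_nocoh`` excludes it; ``muen_over_rho``
    is the mass energy-absorption coefficient.  All in cm^2/g on a strictly
    increasing keV grid.
    """

    material: str
    energies: np.ndarray
    mu_over_rho: np.ndarray
    mu_over_rho_nocoh: np.ndarray
    muen_over_rho: np.ndarray
    _logs: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for arr in (self.mu_over_rho, self.mu_over_rho_nocoh, self.muen_over_rho):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("coefficients must be positive")
        if np.any(self.muen_over_rho > self.mu_over_rho + 1e-12):
            raise ValueError("muen/rho exceeds mu/rho in table "
                             f"for {self.material!r}")
        if not (e[0] <= 10.0 and e[-1] >= 250.0):
            raise ValueError("table must cover at least 10-250 keV")
        self._logs = {
            "e": np.log(e),
            "mu": np.log(self.mu_over_rho),
            "mu_nocoh": np.log(self.mu_over_rho_nocoh),
            "muen": np.log(self.muen_over_rho),
        }

    def _interp(self, energy, key):
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside table range [{lo}, {hi}] keV for "
                f"{self.material!r} (no extrapolation)")
        out = np.exp(np.interp(np.log(e), self._logs["e"], self._logs[key]))
        return float(out) if np.isscalar(energy) else out

    def mu(self, energy):
        """Total mass attenuation coefficient (cm^2/g) at `energy` keV."""
        return self._interp(energy, "mu")

    def mu_nocoh(self, energy):
        """Mass attenuation without the coherent contribution (cm^2/g)."""
        return self._interp(energy, "mu_nocoh")

    def muen(self, energy):
        """Mass energy-absorption coefficient (cm^2/g) at `energy` keV."""
        return self._interp(energy, "muen")


def _data_text(name: str) -> str:
    return (resources.files("kvplan.xsdata") / "data" / name).read_text()


def _load_table_file(table_name: str) -> CoefficientTable:
    rows = []
    for line in _data_text(f"{table_name}.txt").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(x) for x in line.split()])
    arr = np.array(rows)
    return CoefficientTable(table_name, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


@functools.lru_cache(maxsize=None)
def _registry() -> dict[str, Material]:
    entries = yaml.safe_load(_data_text("materials.yaml"))
    reg = {}
    for entry in entries:
        comp = tuple(sorted((int(z), float(w))
                            for z, w in entry["composition"].items()))
        reg[entry["name"]] = Material(
            name=entry["name"],
            composition=comp,
            nominal_density=float(entry["density"]),
            table_name=entry.get("table"),
            fixed_density=bool(entry.get("fixed_density", False)),
        )
    return reg


def list_materials() -> list[str]:
    return sorted(_registry())


def get_material(name: str) -> Material:
    try:
        return _registry()[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; registry has: {list_materials()}"
        ) from None


@functools.lru_cache(maxsize=None)
def get_table(name: str) -> CoefficientTable:
    """Coefficient table for a registry material or element symbol.

    Falls back to elemental additivity over the material's composition when
    no vendored table exists under the requested name.
    """
    reg = _registry()
    if name in reg:
        mat = reg[name]
        if mat.table_name is not None:
            return _load_table_file(mat.table_name)
        return mixture_table(mat)
    try:
        return _load_table_file(name)
    except FileNotFoundError:
        raise KeyError(f"no coefficient table for {name!r}") from None


def mixture_table(material: Material) -> CoefficientTable:
    """Build a table for a mixture by mass-fraction additivity of elements."""
    parts = []
    for z, w in material.composition:
        sym = ELEMENT_SYMBOLS.get(z)
        if sym is None:
            raise KeyError(
                f"no elemental table for Z={z} needed by {material.name!r}")
        parts.append((w, _load_table_file(sym)))
    # merge grids so knots of every component are preserved
    grid = np.unique(np.concatenate([t.energies for _, t in parts]))
    mu = sum(w * t.mu(grid) for w, t in parts)
    mu_nc = sum(w * t.mu_nocoh(grid) for w, t in parts)
    muen = sum(w * t.muen(grid) for w, t in parts)
    return CoefficientTable(material.name, grid, mu, mu_nc, np.minimum(muen, mu))


def _resolve(material) -> tuple[Material, CoefficientTable]:
    if isinstance(material, Material):
        mat = material
        if mat.name in _registry() or mat.table_name:
            table = get_table(mat.table_name or mat.name)
        else:
            table = mixture_table(mat)
    else:
        mat = get_material(material)
        table = get_table(mat.name)
    return mat, table


def mass_attenuation(material, energy, include_coherent: bool = True):
    """Total mass attenuation coefficient mu/rho (cm^2/g).

    `material` is a registry name or a :class:`Material`; `energy` in keV may
    be a scalar or array.  Multiply by density (g/cm^3) for the linear
    coefficient in 1/cm.
    """
    _, table = _resolve(material)
    return table.mu(energy) if include_coherent else table.mu_nocoh(energy)


def mass_energy_absorption(material, energy):
    """Mass energy-absorption coefficient muen/rho (cm^2/g)."""
    _, table = _resolve(material)
    return table.muen(energy)


def electrons_per_gram(material) -> float:
    """Electron density (electrons/g) from the elemental composition."""
    mat = material if isinstance(material, Material) else get_material(material)
    return AVOGADRO * sum(w * z / ATOMIC_WEIGHTS[z] for z, w in mat.composition)
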