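"""Voxel Monte Carlo photon dose engine in the kerma approximation.

Photons are tracked through the voxel phantom with Woodcock (delta) tracking
against a per-energy majorant attenuation coefficient, so no voxel-boundary
ray tracing is needed.  At real interaction sites the channel is chosen from
the photoelectric / Compton / Rayleigh cross-section ratios of the local
material; Compton scattering samples the Klein-Nishina distribution, Rayleigh
redirects with a Thomson-shaped angular law, and the photoelectric channel
absorbs the photon.  Secondary electrons are not transported: at kV energies
their CSDA ranges (< 0.5 mm) are below the voxel size, so collision kerma is
an excellent surrogate for absorbed dose.

Dose is scored with the Woodcock collision-density estimator: every
collision, real or virtual, contributes ``w E (muen/rho) rho / mu_maj`` to
its voxel, which estimates collision kerma with far lower variance than
analog deposition.  An analog energy ledger (emitted / deposited / escaped)
is kept alongside for strict energy accounting.

The per-voxel statistical uncertainty comes from a batch estimator, and runs
are exactly reproducible for a fixed (seed, configuration, inputs): batch
random streams are spawned from the seed, independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import xsdata
from .beams import BeamSetup, sample_source_particles
from .phantom import VoxelPhantom
from .spectrum import KEV_TO_JOULE, Spectrum

__all__ = [
    "RunConfig",
    "DoseGrid",
    "PlaneTally",
    "run_simulation",
    "sample_klein_nishina",
    "write_3ddose",
    "read_3ddose",
]

ELECTRON_REST_KEV = 510.99895


@dataclass
class RunConfig:
    """Engine settings.

    `energy_cutoff_kev`: photons below this deposit locally and die.
    `rayleigh`: include coherent scattering (uses the total attenuation
    column); when off the coherent-free column drives transport.
    `scatter`: when off, every real interaction absorbs the photon, leaving
    pure primary transmission (used by attenuation oracles).
    `majorant_floor_percm`: lower bound on the majorant, useful to force
    virtual collisions (and hence kerma samples) in near-vacuum phantoms.
    """

    n_histories: int = 100_000
    seed: int = 1
    energy_cutoff_kev: float = 5.0
    rayleigh: bool = True
    scatter: bool = True
    splitting: int = 1
    batch_count: int = 10
    majorant_floor_percm: float = 0.0
    tally_plane_z_cm: float | None = None
    tally_radius_cm: float | None = None

    def __post_init__(self):
        if self.n_histories < self.batch_count:
            raise ValueError("need at least one history per batch")
        if self.splitting < 1:
            raise ValueError("splitting factor must be >= 1")


@dataclass
class DoseGrid:
    """Per-voxel dose (Gy per source particle) with relative uncertainty."""

    dose: np.ndarray
    rel_uncertainty: np.ndarray
    histories: int
    voxel_size: tuple[float, float, float]  # mm
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    tallies: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative")

    @property
    def shape(self):
        return self.dose.shape

    def central_axis_profile(self):
        """Dose along z through the central (x, y) column."""
        nx, ny, _ = self.shape
        return self.dose[nx // 2, ny // 2, :]

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.dose * factor, self.rel_uncertainty.copy(),
                        self.histories, self.voxel_size, self.origin,
                        dict(self.tallies))


class PlaneTally:
    """Energy-binned fluence of photons crossing a z = const plane.

    Crossings moving toward +z fill `down`, toward -z fill `up` (the beam by
    convention points down +z into the phantom).  Fluence weighting divides
    by |direction cosine| (capped to avoid grazing-ray blowup).
    """

    def __init__(self, z_cm: float, bin_edges_kev, radius_cm: float | None = None):
        self.z_cm = float(z_cm)
        self.radius_cm = radius_cm
        self.bin_edges = np.asarray(bin_edges_kev, dtype=float)
        self.down = np.zeros(len(self.bin_edges) - 1)
        self.up = np.zeros(len(self.bin_edges) - 1)

    def score(self, pos, new_pos, dirs, energy, weight):
        z0, z1 = pos[:, 2], new_pos[:, 2]
        crossing = (z0 - self.z_cm) * (z1 - self.z_cm) < 0
        if not np.any(crossing):
            return
        if self.radius_cm is not None:
            # crossing point of each straight segment with the plane
            t = (self.z_cm - z0[crossing]) / (z1[crossing] - z0[crossing])
            xy = pos[crossing, :2] + t[:, None] * \
                (new_pos[crossing, :2] - pos[crossing, :2])
            central = np.sum(xy**2, axis=1) <= self.radius_cm**2
            idx = np.nonzero(crossing)[0][central]
            crossing = np.zeros_like(crossing)
            crossing[idx] = True
            if not np.any(crossing):
                return
        e = energy[crossing]
        wz = dirs[crossing, 2]
        w = weight[crossing] / np.maximum(np.abs(wz), 0.02)
        going_down = wz > 0
        self.down += np.histogram(e[going_down], self.bin_edges,
                                  weights=w[going_down])[0]
        self.up += np.histogram(e[~going_down], self.bin_edges,
                                weights=w[~going_down])[0]

    def down_spectrum(self, label="down") -> Spectrum:
        return Spectrum(self.bin_edges, self.down, label)

    def up_spectrum(self, label="up") -> Spectrum:
        return Spectrum(self.bin_edges, self.up, label)


# --- Klein-Nishina sampling -------------------------------------------------

def sample_klein_nishina(energy_kev, rng: np.random.Generator, n: int | None = None):
    """Sample Compton scattering from the Klein-Nishina cross section.

    Uses the standard two-branch composition-rejection method on the energy
    ratio ``eps = E'/E``.  Returns ``(cos_theta, scattered_energy_kev)``;
    scalars for scalar input, arrays of length `n` otherwise.  The scattered
    energy satisfies the Compton relation exactly for the sampled angle.
    """
    scalar = n is None
    m = 1 if scalar else n
    e = np.broadcast_to(np.asarray(energy_kev, dtype=float), (m,)).copy()
    alpha = e / ELECTRON_REST_KEV
    eps0 = 1.0 / (1.0 + 2.0 * alpha)
    cos_t = np.empty(m)
    eps = np.empty(m)
    todo = np.arange(m)
    # branch weights: a1 ~ 1/eps term, a2 ~ eps term
    a1 = np.log(1.0 / eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    while todo.size:
        a1t, a2t, e0t = a1[todo], a2[todo], eps0[todo]
        r1, r2, r3 = rng.random((3, todo.size))
        use_log = r1 < a1t / (a1t + a2t)
        cand = np.where(use_log,
                        e0t * np.exp(a1t * r2),
                        np.sqrt(e0t**2 + (1.0 - e0t**2) * r2))
        one_minus_cos = (1.0 - cand) / (alpha[todo] * cand)
        sin2 = one_minus_cos * (2.0 - one_minus_cos)
        reject = r3 > 1.0 - cand * sin2 / (1.0 + cand**2)
        keep = todo[~reject]
        eps[keep] = cand[~reject]
        cos_t[keep] = 1.0 - one_minus_cos[~reject]
        todo = todo[reject]
    e_out = eps * e
    if scalar:
        return float(cos_t[0]), float(e_out[0])
    return cos_t, e_out


def _sample_thomson_cos(rng: np.random.Generator, n: int):
    # pdf ~ (1 + cos^2)/2 on [-1, 1], sampled by rejection
    out = np.empty(n)
    todo = n
    filled = 0
    while todo:
        c = rng.uniform(-1.0, 1.0, todo)
        acc = rng.random(todo) < 0.5 * (1.0 + c * c)
        k = int(acc.sum())
        out[filled:filled + k] = c[acc]
        filled += k
        todo -= k
    return out


def _rotate_directions(dirs, cos_t, rng):
    """Rotate unit vectors by polar angle arccos(cos_t), uniform azimuth."""
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = rng.uniform(0.0, 2.0 * np.pi, len(cos_t))
    # local frame around each direction
    w = dirs
    helper = np.where(np.abs(w[:, 2:3]) > 0.9,
                      np.array([[0.0, 1.0, 0.0]]),
                      np.array([[0.0, 0.0, 1.0]]))
    u = np.cross(helper, w)
    u /= np.linalg.norm(u, axis=1)[:, None]
    v = np.cross(w, u)
    new = (w * cos_t[:, None]
           + (u * np.cos(phi)[:, None] + v * np.sin(phi)[:, None])
           * sin_t[:, None])
    return new / np.linalg.norm(new, axis=1)[:, None]


# --- material physics lookup ------------------------------------------------

class _PhysicsLookup:
    """Per-material cross sections on a fine log-energy grid."""

    def __init__(self, materials, e_min, e_max, rayleigh: bool, n_grid=256):
        # the vendored tables start at 10 keV; photons between the transport
        # cutoff and the table floor reuse the 10 keV coefficients
        self.e_grid = np.geomspace(max(e_min, 10.0), max(e_max * 1.0001, 11.0),
                                   n_grid)
        self.log_e = np.log(self.e_grid)
        n_mat = len(materials)
        self.mu = np.zeros((n_mat, n_grid))        # transport mu/rho
        self.muen = np.zeros((n_mat, n_grid))
        self.p_compton = np.zeros((n_mat, n_grid))  # channel fractions
        self.p_rayleigh = np.zeros((n_mat, n_grid))
        kn = _kn_total_cm2_per_electron(self.e_grid)
        for i, name in enumerate(materials):
            table = xsdata.get_table(name)
            mat = xsdata.get_material(name)
            total = table.mu(self.e_grid)
            nocoh = table.mu_nocoh(self.e_grid)
            self.muen[i] = table.muen(self.e_grid)
            compton = np.minimum(kn * xsdata.electrons_per_gram(mat), nocoh)
            if rayleigh:
                self.mu[i] = total
                self.p_compton[i] = compton / total
                self.p_rayleigh[i] = (total - nocoh) / total
            else:
                self.mu[i] = nocoh
                self.p_compton[i] = compton / nocoh

    def _idx(self, energy):
        f = np.interp(np.log(energy), self.log_e,
                      np.arange(len(self.e_grid), dtype=float))
        return f

    def lookup(self, arr2d, mat_idx, energy):
        f = self._idx(energy)
        i0 = np.minimum(f.astype(int), arr2d.shape[1] - 2)
        t = f - i0
        a = arr2d[mat_idx, i0]
        b = arr2d[mat_idx, i0 + 1]
        return a * (1 - t) + b * t


def _kn_total_cm2_per_electron(energy_kev):
    """Total Klein-Nishina cross section per electron (cm^2)."""
    a = np.asarray(energy_kev, dtype=float) / ELECTRON_REST_KEV
    r_e2 = 7.94079e-26  # classical electron radius squared, cm^2
    term1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    term2 = np.log(1 + 2 * a) / (2 * a)
    term3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * r_e2 * (term1 + term2 + term3)


# --- engine -----------------------------------------------------------------

def _to_box(pos, dirs, lo, hi):
    """Advance rays outside the box to its surface; returns alive mask."""
    inside = np.all((pos > lo) & (pos < hi), axis=1)
    t_entry = np.zeros(len(pos))
    miss = np.zeros(len(pos), dtype=bool)
    out = ~inside
    if np.any(out):
        p, d = pos[out], dirs[out]
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo - p) / d
            t2 = (hi - p) / d
        tmin = np.nanmax(np.minimum(t1, t2), axis=1)
        tmax = np.nanmin(np.maximum(t1, t2), axis=1)
        ok = (tmax > tmin) & (tmax > 0)
        t_entry[out] = np.where(ok, np.maximum(tmin, 0.0), 0.0)
        miss[out] = ~ok
    pos = pos + (t_entry[:, None] + 1e-7) * dirs
    return pos, ~miss


def run_simulation(phantom: VoxelPhantom, beam: BeamSetup, spectrum: Spectrum,
                   config: RunConfig | None = None) -> DoseGrid:
    """Transport `config.n_histories` source photons and score dose.

    Returns a :class:`DoseGrid` in Gy per source particle whose ``tallies``
    carry the analog energy ledger (keV): ``energy_emitted``,
    ``energy_deposited``, ``energy_escaped``, plus ``n_escaped`` and, when a
    tally plane is configured, the crossing spectra.
    """
    cfg = config or RunConfig()
    shape = phantom.shape
    vox_cm = np.array(phantom.voxel_size) / 10.0
    lo = np.array(phantom.grid.origin) / 10.0
    hi = lo + vox_cm * np.array(shape)

    e_max = float(spectrum.bin_edges[-1])
    physics = _PhysicsLookup(phantom.materials, cfg.energy_cutoff_kev, e_max,
                             cfg.rayleigh)
    mat_idx_grid = phantom.material_index
    rho_grid = phantom.density

    # majorant per energy grid point: max over materials of mu/rho * max rho
    max_rho = np.zeros(len(phantom.materials))
    for i in range(len(phantom.materials)):
        sel = mat_idx_grid == i
        if np.any(sel):
            max_rho[i] = rho_grid[sel].max()
    mu_maj_grid = np.max(physics.mu * max_rho[:, None], axis=0)
    mu_maj_grid = np.maximum(mu_maj_grid, cfg.majorant_floor_percm)

    vol_cm3 = float(np.prod(vox_cm))
    mass_kg = rho_grid * vol_cm3 * 1e-3

    n_per_batch = np.full(cfg.batch_count, cfg.n_histories // cfg.batch_count)
    n_per_batch[: cfg.n_histories % cfg.batch_count] += 1

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.batch_count)
    batch_dose = np.zeros((cfg.batch_count,) + shape)
    ledger = {"energy_emitted": 0.0, "energy_deposited": 0.0,
              "energy_escaped": 0.0, "n_escaped": 0}
    plane = None
    if cfg.tally_plane_z_cm is not None:
        plane = PlaneTally(cfg.tally_plane_z_cm, spectrum.bin_edges,
                           cfg.tally_radius_cm)

    for b, (stream, n_src) in enumerate(zip(streams, n_per_batch)):
        rng = np.random.default_rng(stream)
        n = int(n_src) * cfg.splitting
        weight0 = 1.0 / cfg.splitting
        pos, dirs, energy, weight = sample_source_particles(
            beam, spectrum, n, rng)
        weight = weight * weight0
        ledger["energy_emitted"] += float(np.sum(energy * weight))

        pos, alive = _to_box(pos, dirs, lo, hi)
        ledger["energy_escaped"] += float(np.sum(energy[~alive] * weight[~alive]))
        ledger["n_escaped"] += int(np.count_nonzero(~alive))
        pos, dirs = pos[alive], dirs[alive]
        energy, weight = energy[alive], weight[alive]

        edep = np.zeros(shape)
        while len(pos):
            mu_maj = np.interp(np.log(energy), physics.log_e, mu_maj_grid)
            step = -np.log(rng.random(len(pos))) / mu_maj
            new_pos = pos + step[:, None] * dirs
            if plane is not None:
                plane.score(pos, new_pos, dirs, energy, weight)
            inside = np.all((new_pos > lo) & (new_pos < hi), axis=1)
            esc = ~inside
            ledger["energy_escaped"] += float(np.sum(energy[esc] * weight[esc]))
            ledger["n_escaped"] += int(np.count_nonzero(esc))
            pos, dirs = new_pos[inside], dirs[inside]
            energy, weight, mu_maj = energy[inside], weight[inside], mu_maj[inside]
            if not len(pos):
                break

            ijk = ((pos - lo) / vox_cm).astype(int)
            np.clip(ijk, 0, np.array(shape) - 1, out=ijk)
            flat = np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), shape)
            mat = mat_idx_grid.ravel()[flat].astype(int)
            rho = rho_grid.ravel()[flat]

            # kerma collision estimator at every (real or virtual) collision
            muen = physics.lookup(physics.muen, mat, energy)
            np.add.at(edep.ravel(), flat,
                      weight * energy * muen * rho / mu_maj)

            mu_real = physics.lookup(physics.mu, mat, energy) * rho
            r = rng.random(len(pos))
            real = r < mu_real / mu_maj
            if not np.any(real):
                continue

            # channel selection among real interactions
            idx_real = np.nonzero(real)[0]
            e_r = energy[idx_real]
            m_r = mat[idx_real]
            p_c = physics.lookup(physics.p_compton, m_r, e_r)
            p_r = physics.lookup(physics.p_rayleigh, m_r, e_r)
            u = rng.random(len(idx_real))
            is_compton = u < p_c
            is_rayleigh = (~is_compton) & (u < p_c + p_r)
            # photoelectric: the rest -> absorb
            absorbed = np.zeros(len(pos), dtype=bool)
            dep_local = np.zeros(len(pos))

            if not cfg.scatter:
                absorbed[idx_real] = True
                dep_local[idx_real] = e_r
            else:
                photo_idx = idx_real[~is_compton & ~is_rayleigh]
                absorbed[photo_idx] = True
                dep_local[photo_idx] = energy[photo_idx]

                c_idx = idx_real[is_compton]
                if len(c_idx):
                    cos_t, e_new = sample_klein_nishina(
                        energy[c_idx], rng, len(c_idx))
                    dep_local[c_idx] = energy[c_idx] - e_new
                    energy[c_idx] = e_new
                    dirs[c_idx] = _rotate_directions(dirs[c_idx], cos_t, rng)
                    below = np.zeros(len(pos), dtype=bool)
                    below[c_idx] = e_new < cfg.energy_cutoff_kev
                    dep_local[below] += energy[below]
                    absorbed |= below

                r_idx = idx_real[is_rayleigh]
                if len(r_idx):
                    cos_t = _sample_thomson_cos(rng, len(r_idx))
                    dirs[r_idx] = _rotate_directions(dirs[r_idx], cos_t, rng)

            ledger["energy_deposited"] += float(np.sum(dep_local * weight))
            keep = ~absorbed
            pos, dirs = pos[keep], dirs[keep]
            energy, weight = energy[keep], weight[keep]

        batch_dose[b] = edep * KEV_TO_JOULE / mass_kg / float(n_src)

    dose = batch_dose.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = batch_dose.std(axis=0, ddof=1) / np.sqrt(cfg.batch_count)
        rel = np.where(dose > 0, se / np.where(dose > 0, dose, 1.0), 0.0)
    tallies = dict(ledger)
    if plane is not None:
        tallies["plane_down"] = plane.down_spectrum()
        tallies["plane_up"] = plane.up_spectrum()
    if ledger["energy_emitted"] > 0 and \
            tallies["energy_escaped"] / ledger["energy_emitted"] > 0.999:
        import warnings
        warnings.warn("beam missed the phantom almost entirely", stacklevel=2)
    return DoseGrid(dose, rel, cfg.n_histories,
                    tuple(phantom.voxel_size), tuple(phantom.grid.origin),
                    tallies)


# --- 3ddose text I/O --------------------------------------------------------

def write_3ddose(grid: DoseGrid, path) -> None:
    """Write the EGSnrc 3ddose text layout.

    Line 1: voxel counts nx ny nz; lines 2-4: the x/y/z voxel boundary
    coordinates (cm, n+1 each); line 5: the nx*ny*nz dose values in Gy per
    particle (x fastest); line 6: the relative errors in the same order.
    """
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{nx} {ny} {nz}\n")
        for axis in range(3):
            o = grid.origin[axis] / 10.0
            v = grid.voxel_size[axis] / 10.0
            bounds = o + v * np.arange(grid.shape[axis] + 1)
            fh.write(" ".join(f"{b:.6g}" for b in bounds) + "\n")
        dose_flat = grid.dose.transpose(2, 1, 0).ravel()
        err_flat = grid.rel_uncertainty.transpose(2, 1, 0).ravel()
        fh.write(" ".join(f"{d:.8e}" for d in dose_flat) + "\n")
        fh.write(" ".join(f"{e:.6e}" for e in err_flat) + "\n")


def read_3ddose(path) -> DoseGrid:
    """Read the EGSnrc 3ddose text layout written by :func:`write_3ddose`."""
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(tokens)
    try:
        nx, ny, nz = int(next(it)), int(next(it)), int(next(it))
    except (StopIteration, ValueError) as exc:
        raise ValueError(f"{path}: malformed 3ddose header") from exc
    bounds = []
    for n in (nx, ny, nz):
        bounds.append(np.array([float(next(it)) for _ in range(n + 1)]))
    n_vox = nx * ny * nz
    dose = np.array([float(next(it)) for _ in range(n_vox)])
    err = np.array([float(next(it)) for _ in range(n_vox)])
    dose = dose.reshape(nz, ny, nx).transpose(2, 1, 0)
    err = err.reshape(nz, ny, nx).transpose(2, 1, 0)
    voxel = tuple(float((b[1] - b[0]) * 10.0) for b in bounds)
    origin = tuple(float(b[0] * 10.0) for b in bounds)
    return DoseGrid(dose, err, histories=0, voxel_size=voxel, origin=origin)
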