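"""End-to-end planning pipeline: segment -> beam -> simulate -> normalize -> analyze.

A single YAML configuration drives the clinical workflow: phantom
construction (watertank, three-compartment, or an egsphant-style file with
optional HU overwrite), beam setup from the applicator catalogue or an
explicit aperture, spectrum generation or loading, Monte Carlo transport,
absolute dose normalization against the unit output, and the requested
analyses (PDD, profiles, DVH).  Every run writes a 3ddose file and a JSON
manifest (tool version, config snapshot, input hashes, seed, timestamps) so
results are traceable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, beams, dosimetry, phantom, spectrum, transport

__all__ = ["RunManifest", "validate_config", "run_pipeline", "ConfigError"]


class ConfigError(ValueError):
    """Configuration problem; the message names the failing field path."""


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    input_hashes: dict
    started: str
    finished: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _require(cfg: dict, path: str, types=None):
    node = cfg
    for part in path.split("."):
        if not isinstance(node, dict) or part not in node:
            raise ConfigError(f"missing required config field: {path}")
        node = node[part]
    if types is not None and not isinstance(node, types):
        raise ConfigError(f"config field {path} has wrong type "
                          f"({type(node).__name__})")
    return node


def validate_config(cfg: dict) -> list[str]:
    """Validate a pipeline config; returns a list of notes, raises on error."""
    notes = []
    _require(cfg, "beam", dict)
    if "applicator" in cfg["beam"]:
        beams.get_applicator(str(cfg["beam"]["applicator"]))
    else:
        _require(cfg, "beam.kvp", (int, float))
        _require(cfg, "beam.ssd_cm", (int, float))
        _require(cfg, "beam.aperture", (list, tuple))
    spec_cfg = cfg.get("spectrum", {})
    if "file" not in spec_cfg:
        kvp = spec_cfg.get("kvp", cfg["beam"].get("kvp"))
        if kvp is None and "applicator" not in cfg["beam"]:
            raise ConfigError("missing required config field: spectrum.kvp")
        for layer in spec_cfg.get("filtration", []):
            from . import xsdata
            xsdata.get_material(str(layer[0]))
    ph = cfg.get("phantom", {"type": "watertank"})
    kind = ph.get("type", "watertank")
    if kind not in ("watertank", "three_compartment", "file"):
        raise ConfigError(f"phantom.type {kind!r} not one of "
                          "watertank|three_compartment|file")
    if kind == "file":
        _require(cfg, "phantom.path", str)
    run = cfg.get("run", {})
    if int(run.get("histories", 10000)) < int(run.get("batches", 10)):
        raise ConfigError("run.histories must be >= run.batches")
    if "normalize" in cfg:
        _require(cfg, "normalize.output_gy_per_mu", (int, float))
        _require(cfg, "normalize.mu", (int, float))
    if not cfg.get("analyses"):
        notes.append("no analyses requested; only raw dose will be written")
    return notes


def _build_beam(cfg: dict) -> tuple[beams.BeamSetup, float]:
    bc = cfg["beam"]
    if "applicator" in bc:
        app = beams.get_applicator(str(bc["applicator"]))
    else:
        aperture = tuple(
            [bc["aperture"][0]] + [float(x) for x in bc["aperture"][1:]])
        app = beams.Applicator("custom", float(bc["kvp"]),
                               float(bc["ssd_cm"]), aperture)
    cutout = None
    if "cutout" in bc:
        cc = bc["cutout"]
        if "shape" in cc:
            cutout = beams.cutout_polygon(cc["shape"],
                                          float(cc.get("size_cm", 6.0)))
        else:
            from shapely.geometry import Polygon
            cutout = Polygon([(float(x), float(y)) for x, y in cc["vertices"]])
    setup = beams.BeamSetup(
        applicator=app,
        exit_window_center=tuple(bc.get("exit_window_center", (0.0, 0.0, 0.0))),
        theta=float(bc.get("theta", 0.0)),
        phi=float(bc.get("phi", 0.0)),
        phicol=float(bc.get("phicol", 0.0)),
        cutout=cutout,
    )
    return setup, app.kvp


def _build_spectrum(cfg: dict, kvp: float) -> spectrum.Spectrum:
    sc = cfg.get("spectrum", {})
    if "file" in sc:
        return spectrum.read_spectrum(sc["file"])
    sp = spectrum.generate_tube_spectrum(float(sc.get("kvp", kvp)))
    layers = [(str(m), float(t)) for m, t in sc.get("filtration", [])]
    return spectrum.filter_spectrum(sp, layers)


def _build_phantom(cfg: dict):
    ph = cfg.get("phantom", {"type": "watertank"})
    kind = ph.get("type", "watertank")
    if kind == "watertank":
        return phantom.make_watertank(
            tuple(ph.get("size_cm", (20.0, 20.0, 15.0))),
            tuple(ph.get("voxel_mm", (2.0, 2.0, 2.0)))), None
    if kind == "three_compartment":
        p, centers = phantom.make_three_compartment(
            tuple(ph.get("materials", ("water", "adipose", "muscle"))))
        return p, centers
    p = phantom.read_phantom(ph["path"])
    return p, None


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute the full workflow described by a YAML config file.

    Returns the output directory, which contains ``dose.3ddose``, any
    requested analysis CSV/JSON files, and ``manifest.json``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)

    out = Path(out_dir or cfg.get("out_dir", config_path.stem + "_out"))
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    hashes = {config_path.name:
              hashlib.sha256(config_path.read_bytes()).hexdigest()}

    beam, kvp = _build_beam(cfg)
    spec = _build_spectrum(cfg, kvp)
    phant, centers = _build_phantom(cfg)

    run_cfg = transport.RunConfig(
        n_histories=int(cfg.get("run", {}).get("histories", 50000)),
        seed=int(cfg.get("run", {}).get("seed", 1)),
        batch_count=int(cfg.get("run", {}).get("batches", 10)),
    )
    dose = transport.run_simulation(phant, beam, spec, run_cfg)

    results = {}
    if "normalize" in cfg:
        nc = cfg["normalize"]
        if "water_surface_dose" in nc:
            d_water = float(nc["water_surface_dose"])
        else:
            # matching watertank run with the same beam and spectrum
            tank = phantom.make_watertank(
                tuple(cfg.get("phantom", {}).get("size_cm", (20.0, 20.0, 15.0))),
                tuple(cfg.get("phantom", {}).get("voxel_mm", (2.0, 2.0, 2.0))))
            d_ref = transport.run_simulation(tank, beam, spec, run_cfg)
            d_water = float(d_ref.central_axis_profile()[0])
        dose = dosimetry.absolute_dose(dose, d_water,
                                       float(nc["output_gy_per_mu"]),
                                       float(nc["mu"]))
        results["normalization"] = {"water_surface_dose_gy_per_particle":
                                    d_water}

    transport.write_3ddose(dose, out / "dose.3ddose")

    for analysis in cfg.get("analyses", []):
        kind = analysis["type"] if isinstance(analysis, dict) else analysis
        if kind == "pdd":
            curve = dosimetry.extract_pdd(dose)
            np.savetxt(out / "pdd.csv",
                       np.column_stack([curve.depths_mm, curve.values]),
                       delimiter=",", header="depth_mm,pdd_percent")
        elif kind == "profile":
            depth = float(analysis.get("depth_mm", 10.0)) \
                if isinstance(analysis, dict) else 10.0
            prof = dosimetry.extract_profile(dose, depth)
            np.savetxt(out / f"profile_{depth:g}mm.csv",
                       np.column_stack([prof.offsets_mm, prof.values]),
                       delimiter=",", header="offset_mm,relative_dose")
        elif kind == "dvh":
            levels, volume = dosimetry.dvh(dose)
            np.savetxt(out / "dvh.csv", np.column_stack([levels, volume]),
                       delimiter=",", header="dose,volume_percent")
        elif kind == "compartment_means":
            if centers is None:
                raise ConfigError(
                    "compartment_means requires a three_compartment phantom")
            means = {}
            vox = np.array(phant.voxel_size) / 10.0
            lo = np.array(phant.grid.origin) / 10.0
            for name, c in centers.items():
                ijk = ((np.array(c) - lo) / vox).astype(int)
                region = dose.dose[ijk[0] - 1:ijk[0] + 2,
                                   ijk[1] - 1:ijk[1] + 2,
                                   ijk[2] - 1:ijk[2] + 2]
                means[name] = float(region.mean())
            results["compartment_mean_dose"] = means
        else:
            raise ConfigError(f"unknown analysis type {kind!r}")

    if results:
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)

    manifest = RunManifest(
        version=__version__, seed=run_cfg.seed, config=cfg,
        input_hashes=hashes, started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"))
    manifest.write(out / "manifest.json")
    return out
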