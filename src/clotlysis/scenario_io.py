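"""Scenario configuration, reference scenarios and output writers.

Configs are YAML with explicit unit suffixes on every physical quantity
("50 nM", "2.5 mm", "1 Pa"); values are normalized to internal units
(µM, m, s, Pa) on load and unknown keys are rejected wholesale.  The
shipped reference scenarios cover every simulation tier with no external
data.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError
from .flow2d import FluidProps, build_channel
from .history import SimulationHistory
from .kinetics import KineticParameters, MicrostructureParams, WellMixedState, simulate_well_mixed, time_to_lysis
from .microstructure import SPECIES
from .transport1d import Grid1D, Scenario1D, dose_sweep_1d, front_velocity, simulate_1d
from .coupled2d import CoupledScenario, compare_pressure_drops, peak_recirculation, simulate_occlusion_lysis

TIERS = ("well_mixed", "transport1d", "coupled2d", "dose_sweep", "pressure_sweep")

# schema: section -> key -> (dimension | "float" | "int" | "list" | "str")
_SCHEMA = {
    "kinetics": {
        "k_ads_tPA": "float", "k_ads_PLG": "float", "k_ads_PLS": "float",
        "k_rev_tPA": "float", "k_rev_PLG": "float", "k_rev_PLS": "float",
        "k2": "float", "K_M": "concentration", "k_cat": "float",
        "gamma": "float", "kappa": "float", "k_AP": "float",
        "plasmin_decay": "float",
    },
    "microstructure": {
        "fibrin_density": "mass_concentration",
        "fibre_radius_initial": "length",
        "fibrin_monomer_molar_mass": "float",
        "fibre_protein_density": "mass_concentration",
        "permeability_cap": "permeability",
        "voidage_lysed_threshold": "float",
    },
    "well_mixed": {
        "tPA": "concentration", "PLG": "concentration", "AP": "concentration",
        "t_end": "time",
    },
    "transport1d": {
        "length": "length", "n_cells": "int", "clot_start": "length",
        "clot_end": "length", "tPA": "concentration", "PLG": "concentration",
        "D": "diffusivity", "t_end": "time", "doses": "list",
        "snapshot_times": "list",
    },
    "coupled": {
        "height": "length", "length": "length", "clot_x0": "length",
        "clot_width": "length", "nx": "int", "ny": "int",
        "dp": "pressure", "dp_list": "list", "tPA": "concentration",
        "PLG": "concentration", "D": "diffusivity", "dt": "time",
        "t_max": "time", "btr_stop": "float",
        "rho": "float", "mu": "float",
    },
    "output": {"directory": "str", "formats": "list"},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated, unit-normalized scenario description."""

    tier: str
    name: str = "scenario"
    kinetics: dict = field(default_factory=dict)
    microstructure: dict = field(default_factory=dict)
    well_mixed: dict = field(default_factory=dict)
    transport1d: dict = field(default_factory=dict)
    coupled: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    # ---- construction of model objects ------------------------------------

    def kinetic_parameters(self) -> KineticParameters:
        kw = dict(self.kinetics)
        k_ads = {s: kw.pop(f"k_ads_{s}", None) for s in SPECIES}
        k_rev = {s: kw.pop(f"k_rev_{s}", None) for s in SPECIES}
        kp = KineticParameters()
        k_ads = {s: kp.k_ads[s] if k_ads[s] is None else k_ads[s] for s in SPECIES}
        k_rev = {s: kp.k_rev[s] if k_rev[s] is None else k_rev[s] for s in SPECIES}
        return KineticParameters(k_ads=k_ads, k_rev=k_rev, **kw)

    def microstructure_parameters(self) -> MicrostructureParams:
        return MicrostructureParams(**self.microstructure)

    def scenario_1d(self) -> Scenario1D:
        p = dict(self.transport1d)
        grid = Grid1D(
            length=p.pop("length", 5.5e-3),
            n_cells=p.pop("n_cells", 220),
            clot_start=p.pop("clot_start", 0.0),
            clot_end=p.pop("clot_end", 4.5e-3),
        )
        p.pop("doses", None)
        snaps = p.pop("snapshot_times", None)
        kw = dict(
            grid=grid, kp=self.kinetic_parameters(),
            mp=self.microstructure_parameters(),
            inlet_tPA=p.pop("tPA", 0.05), inlet_PLG=p.pop("PLG", 2.0),
        )
        if "D" in p:
            kw["D"] = p.pop("D")
        if "t_end" in p:
            kw["t_end"] = p.pop("t_end")
        if snaps is not None:
            kw["snapshot_times"] = tuple(float(s) for s in snaps)
        return Scenario1D(**kw)

    def scenario_2d(self) -> CoupledScenario:
        p = dict(self.coupled)
        grid = build_channel(
            height=p.pop("height", 5e-3), length=p.pop("length", 25e-3),
            clot_x0=p.pop("clot_x0", 10e-3), clot_width=p.pop("clot_width", 2.5e-3),
            nx=p.pop("nx", 150), ny=p.pop("ny", 30),
        )
        fluid = FluidProps(rho=p.pop("rho", 1050.0), mu=p.pop("mu", 3.5e-3))
        p.pop("dp_list", None)
        kw = dict(grid=grid, kp=self.kinetic_parameters(),
                  mp=self.microstructure_parameters(), fluid=fluid)
        for src, dst in (("dp", "dp"), ("tPA", "inlet_tPA"), ("PLG", "inlet_PLG"),
                         ("D", "D"), ("dt", "dt"), ("t_max", "t_max"),
                         ("btr_stop", "btr_stop")):
            if src in p:
                kw[dst] = p.pop(src)
        return CoupledScenario(**kw)

    # ---- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tier": self.tier, "name": self.name,
            **{k: dict(getattr(self, k)) for k in
               ("kinetics", "microstructure", "well_mixed", "transport1d",
                "coupled", "output") if getattr(self, k)},
        }

    def save(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _normalize_section(section: str, raw: dict) -> dict:
    from .units import parse_quantity

    schema = _SCHEMA[section]
    out, bad = {}, []
    for key, value in raw.items():
        if key not in schema:
            bad.append(f"{section}.{key}")
            continue
        kind = schema[key]
        if kind == "int":
            out[key] = int(value)
        elif kind == "float":
            out[key] = float(value)
        elif kind == "list":
            out[key] = list(value)
        elif kind == "str":
            out[key] = str(value)
        else:
            out[key] = parse_quantity(value, kind, key=f"{section}.{key}")
    if bad:
        raise ConfigError(f"unknown config keys: {', '.join(sorted(bad))}")
    return out


def config_from_dict(data: dict) -> ScenarioConfig:
    """Validate and unit-normalize a raw config mapping."""
    data = dict(data)
    tier = data.pop("tier", None)
    if tier not in TIERS:
        raise ConfigError(f"tier must be one of {TIERS}, got {tier!r}")
    name = str(data.pop("name", "scenario"))
    sections, bad = {}, []
    for key, value in data.items():
        if key not in _SCHEMA:
            bad.append(key)
            continue
        if not isinstance(value, dict):
            raise ConfigError(f"section {key!r} must be a mapping")
        sections[key] = _normalize_section(key, value)
    if bad:
        raise ConfigError(f"unknown config sections: {', '.join(sorted(bad))}")
    cfg = ScenarioConfig(tier=tier, name=name, **sections)
    _validate_physical(cfg)
    return cfg


def _validate_physical(cfg: ScenarioConfig) -> None:
    problems = []
    if cfg.coupled.get("dp", 0.0) < 0:
        problems.append("coupled.dp must be >= 0")
    for key in ("tPA", "PLG", "AP"):
        for section in ("well_mixed", "transport1d", "coupled"):
            v = getattr(cfg, section).get(key)
            if v is not None and v < 0:
                problems.append(f"{section}.{key} must be >= 0")
    # construct parameter objects so their own invariants run
    try:
        cfg.kinetic_parameters()
        cfg.microstructure_parameters()
    except (ConfigError, ValueError) as exc:
        problems.append(str(exc))
    if problems:
        raise ConfigError("; ".join(problems))


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return config_from_dict(data)


def reference_scenarios() -> dict:
    """The shipped, fully self-contained reference scenarios."""
    out = {}
    out["wellmixed-reference"] = config_from_dict({
        "tier": "well_mixed", "name": "wellmixed-reference",
        "well_mixed": {"tPA": "50 nM", "PLG": "2 uM", "AP": "1 uM",
                       "t_end": "200 s"},
    })
    # thin-clot validation conditions: 5.88 µM fibrin, surface MM pair
    out["wellmixed-validation"] = config_from_dict({
        "tier": "well_mixed", "name": "wellmixed-validation",
        "kinetics": {"K_M": "2.42 uM", "k2": 0.22},
        "microstructure": {"fibrin_density": "2.0 mg/ml"},
        "well_mixed": {"tPA": "50 nM", "PLG": "2 uM", "AP": "1 uM",
                       "t_end": "1 h"},
    })
    out["1d-reference"] = config_from_dict({
        "tier": "transport1d", "name": "1d-reference",
        "transport1d": {"length": "5.5 mm", "n_cells": 220,
                        "clot_start": "0 mm", "clot_end": "4.5 mm",
                        "tPA": "50 nM", "PLG": "2 uM", "t_end": "95 min"},
    })
    out["1d-dose-sweep"] = config_from_dict({
        "tier": "dose_sweep", "name": "1d-dose-sweep",
        "transport1d": {"length": "7 mm", "n_cells": 280,
                        "clot_start": "0 mm", "clot_end": "6 mm",
                        "t_end": "90 min",
                        "doses": ["1 nM", "10 nM", "100 nM", "1000 nM"]},
    })
    for dp in (1, 5, 10, 20):
        out[f"occlusion-{dp}pa"] = config_from_dict({
            "tier": "coupled2d", "name": f"occlusion-{dp}pa",
            "coupled": {"height": "5 mm", "length": "25 mm",
                        "clot_x0": "10 mm", "clot_width": "2.5 mm",
                        "nx": 150, "ny": 30, "dp": f"{dp} Pa",
                        "tPA": "50 nM", "PLG": "2 uM"},
        })
    out["pressure-sweep"] = config_from_dict({
        "tier": "pressure_sweep", "name": "pressure-sweep",
        "coupled": {"height": "5 mm", "length": "25 mm",
                    "clot_x0": "10 mm", "clot_width": "2.5 mm",
                    "nx": 150, "ny": 30,
                    "dp_list": [1.0, 5.0, 10.0, 20.0],
                    "tPA": "50 nM", "PLG": "2 uM"},
    })
    return out


# ---- runners ---------------------------------------------------------------


def run_scenario(cfg: ScenarioConfig, progress=None):
    """Execute a scenario; returns (history-or-None, metrics dict)."""
    kp = cfg.kinetic_parameters()
    mp = cfg.microstructure_parameters()
    if cfg.tier == "well_mixed":
        wm = cfg.well_mixed
        init = WellMixedState.initial(
            kp, mp, tPA=wm.get("tPA", 0.05), PLG_total=wm.get("PLG", 2.0),
            AP=wm.get("AP", 1.0))
        hist = simulate_well_mixed(init, kp, mp, wm.get("t_end", 200.0))
        metrics = {
            "time_to_lysis_95": time_to_lysis(hist, 0.95),
            "time_to_lysis_99": time_to_lysis(hist, 0.99),
            "final_lysis_fraction": float(hist.column("lysis_fraction")[-1]),
        }
        return hist, metrics
    if cfg.tier == "transport1d":
        sc = cfg.scenario_1d()
        hist = simulate_1d(sc)
        metrics = {"front_velocity_um_min": front_velocity(hist)}
        return hist, metrics
    if cfg.tier == "dose_sweep":
        sc = cfg.scenario_1d()
        doses = cfg.transport1d.get("doses", [0.001, 0.01, 0.1, 1.0])
        from .units import parse_quantity
        doses = [parse_quantity(d, "concentration", key="dose") for d in doses]
        table = dose_sweep_1d(doses, sc)
        return None, {"dose_velocity_table": table}
    if cfg.tier == "coupled2d":
        sc = cfg.scenario_2d()
        hist, met = simulate_occlusion_lysis(sc, progress=progress)
        metrics = {
            "t_start": met.t_start,
            "t_breakthrough": met.t_breakthrough,
            "breakthrough_duration": met.t_breakthrough - met.t_start,
            "peak_recirculation": peak_recirculation(hist, met),
            "asymmetry_at": met.asymmetry_at,
            "final_lysis_fraction": met.final_lysis_fraction,
        }
        return hist, metrics
    if cfg.tier == "pressure_sweep":
        base = cfg.scenario_2d()
        dp_list = cfg.coupled.get("dp_list", [1.0, 5.0, 10.0, 20.0])
        reports = compare_pressure_drops(dp_list, base, progress=progress)
        metrics = {"pressure_reports": [
            {k: v for k, v in r.items() if k not in ("history", "metrics")}
            for r in reports
        ]}
        return None, metrics
    raise ConfigError(f"unknown tier {cfg.tier!r}")


# ---- writers ---------------------------------------------------------------


def write_vtk_structured(path, grid, fields: dict) -> Path:
    """Minimal legacy-ASCII VTK structured-points writer for 2-D cell data."""
    path = Path(path)
    nx, ny = grid.nx, grid.ny
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nclotlysis snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {grid.dx:g} {grid.dy:g} 1\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if arr.shape != (nx, ny):
                continue
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK cell order: x fastest
            for j in range(ny):
                fh.write(" ".join(f"{arr[i, j]:.6g}" for i in range(nx)) + "\n")
    return path


def write_outputs(history, metrics, cfg: ScenarioConfig, outdir,
                  seed=None) -> list:
    """Write CSV time series, VTK snapshots (2-D) and a JSON run manifest.

    Returns the list of files written.  Re-running with the same config
    reproduces byte-identical CSV output (the model is deterministic).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    prefix = cfg.name

    if history is not None and len(history) > 0:
        csv_path = outdir / f"{prefix}-timeseries.csv"
        history.to_csv(csv_path)
        written.append(csv_path)
        for t, snap in history.snapshots:
            label = snap.get("btr")
            tag = f"btr{label:.2f}" if isinstance(label, float) else f"t{t:.0f}s"
            arrays = {k: v for k, v in snap.items()
                      if isinstance(v, np.ndarray) and v.ndim == 2}
            if arrays:
                g = cfg.scenario_2d().grid
                p = write_vtk_structured(outdir / f"{prefix}-{tag}.vtk", g, arrays)
                written.append(p)
            else:  # 1-D profile snapshot -> CSV
                p = outdir / f"{prefix}-profile-{t:.0f}s.csv"
                names = [k for k in snap if isinstance(snap[k], np.ndarray)]
                with open(p, "w", newline="") as fh:
                    w = csv.writer(fh)
                    w.writerow(names)
                    for row in zip(*[snap[k] for k in names]):
                        w.writerow([repr(float(x)) for x in row])
                written.append(p)
    elif history is not None:
        warnings.warn("empty history: writing manifest only")

    manifest = {
        "name": cfg.name,
        "tier": cfg.tier,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "seed": seed,
        "metrics": _jsonable(metrics),
        "files": [p.name for p in written],
        "wall_time": _time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mpath = outdir / f"{prefix}-manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mpath)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
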