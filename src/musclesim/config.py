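"""TOML study configuration: load, resolve against defaults, dump.

A config file holds optional blocks ``[geometry]``, ``[schedule]``,
``[conduction]``, ``[stimulus]``, ``[mechanics]``, ``[activation]`` and
``[study]``; absent keys fall back to the package defaults, and every
run writes the fully resolved config next to its outputs together with
the seed and a content hash, so runs are reproducible from the output
directory alone.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

from .cell_models import ActivationParams
from .geometry import build_cube_geometry
from .mechanics import ConstitutiveParams
from .monodomain import FiberConductionParams, StimulusProtocol
from .splitting import SplittingSchedule

__all__ = ["load_config", "resolve", "default_config", "write_resolved"]


def default_config() -> dict[str, Any]:
    return {
        "geometry": {
            "extent": [1.0, 1.0, 1.0],
            "elements3d": [2, 2, 2],
            "fiber_axis": "x",
            "fibers_per_cross_section_element": [3, 3],
            "elements_per_fiber_per_3d_element": 3,
        },
        "schedule": {
            "dt_3d": 1.0, "N": 250, "K": 2,
            "scheme": "strang", "reaction_integrator": "heun",
        },
        "conduction": {"sigma_eff": 3.828, "A_m": 500.0, "C_m": 1.0},
        "stimulus": {
            "amplitude": 1200.0, "t_start": 0.0, "t_end": 0.1,
            "target": "midpoint",
        },
        "mechanics": {
            "c1": 3.0, "c2": 1.0, "b1": 1.5, "d": 4.0,
            "sigma_max": 30.0, "a0": [1.0, 0.0, 0.0],
            "active_normalized": True,
        },
        "activation": {
            "l_opt": 1.1, "l_min": 0.635, "l_max": 1.85, "l_hs_ref": 1.0,
        },
        "study": {"t_end": 1.0, "solver": "thomas", "seed": 0},
    }


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Read a TOML config and merge it over the defaults (block-wise)."""
    cfg = default_config()
    if path is not None:
        with open(path, "rb") as f:
            user = tomllib.load(f)
        for block, values in user.items():
            cfg.setdefault(block, {}).update(values)
    return cfg


def resolve(cfg: dict[str, Any]) -> dict[str, Any]:
    """Instantiate the domain objects described by a config dict."""
    g = cfg["geometry"]
    return {
        "geom": build_cube_geometry(
            extent=tuple(g["extent"]),
            elements3d=tuple(g["elements3d"]),
            fiber_axis=g["fiber_axis"],
            fibers_per_cross_section_element=tuple(
                g["fibers_per_cross_section_element"]),
            elements_per_fiber_per_3d_element=g[
                "elements_per_fiber_per_3d_element"],
        ),
        "schedule": SplittingSchedule(**cfg["schedule"]),
        "conduction": FiberConductionParams(**cfg["conduction"]),
        "protocol": StimulusProtocol(**cfg["stimulus"]),
        "mech_params": ConstitutiveParams(
            **{**cfg["mechanics"], "a0": tuple(cfg["mechanics"]["a0"])}),
        "act_params": ActivationParams(**cfg["activation"]),
    }


def write_resolved(cfg: dict[str, Any], outdir: str | Path,
                   seed: int) -> Path:
    """Write the resolved config (with seed and content hash) as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = dict(cfg)
    payload["study"] = {**cfg.get("study", {}), "seed": seed}
    text = json.dumps(payload, indent=1, sort_keys=True)
    digest = hashlib.sha256(text.encode()).hexdigest()[:16]
    out = outdir / "resolved_config.json"
    out.write_text(json.dumps(
        {"config": payload, "config_hash": digest}, indent=1, sort_keys=True))
    return out
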