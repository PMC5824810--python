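"""Run configuration: one structured YAML file holds every physical
constant and simulation setting; nothing physical is hard-coded in the
pipeline."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from .energetics import MembraneMechanics
from .geometry import ScaffoldDesign

__all__ = ["DEFAULT_CONFIG", "load_config", "resolve_config", "config_hash",
           "mechanics_from_config", "designs_from_config"]

# Defaults mirror the study conditions: three scaffold designs (H/Q/L,
# 110 nm arcs, ~1800 nm^2 footprint), a DOPC bilayer, per-design apparent
# dissociation constants, and the generator settings of the synthetic
# tables.
DEFAULT_CONFIG: dict[str, Any] = {
    "scaffolds": {
        "H3": {"angle_deg": 131.0, "radius_nm": 46.0, "arc_length_nm": 110.0,
               "footprint_nm2": 1800.0, "n_anchors": 3, "anchor_face": "concave",
               "kd_nm": 2.0},
        "Q3": {"angle_deg": 73.0, "radius_nm": 84.0, "arc_length_nm": 110.0,
               "footprint_nm2": 1800.0, "n_anchors": 3, "anchor_face": "concave",
               "kd_nm": 0.68},
        "L3": {"angle_deg": None, "radius_nm": None, "arc_length_nm": 110.0,
               "footprint_nm2": 1800.0, "n_anchors": 3, "anchor_face": "concave",
               "kd_nm": 0.39},
    },
    "mechanics": {
        "kappa_kBT": 23.1,
        "alpha": 3.0 / 3.141592653589793,
        "c0_per_nm": 0.0,
        "thickness_nm": 4.0,
        "delta_a0_nm2": 0.0,
        "temperature_K": 298.15,
    },
    "fcs": {
        "r0_nm": 207.0,
        "r0_sd_nm": 7.0,
        "dye": "Alexa488",
        "d_ref_um2_s": 414.0,
        "d_ref_temperature_K": 298.15,
        "working_temperature_K": 300.65,
        "scaffold_length_nm": 110.0,
    },
    "fitting": {
        "pooled": True,
        "ci_level": 0.95,
        "tubulation_targets": [0.5, 0.8],
    },
    "simulation": {
        "seed": 0,
        "binding": {"intensity_cv": 0.2, "n_guvs_per_conc": 15,
                    "true_imax": 1000.0,
                    "concentrations_nM": [0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0]},
        "fcs": {"true_n": 12.0, "true_tau_d_s": 0.020, "noise_sd": 0.002,
                "lag_min_s": 1e-4, "lag_decades": 4.0, "points_per_decade": 11},
        "morphology": {"sigma50_per_um2": 62.0, "hill_slope": 4.0,
                       "n_guvs_per_density": 60,
                       "densities_per_um2": [10, 30, 50, 70, 90, 120]},
        "tube": {"mean_diameter_nm": 220.0, "sd_nm": 70.0, "n_sections": 35},
    },
}


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def resolve_config(overrides: dict | None = None) -> dict:
    """Defaults overlaid with user overrides (nested dict merge)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file on top of the defaults."""
    overrides = None
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    return resolve_config(overrides)


def config_hash(cfg: dict) -> str:
    """Stable short hash of the resolved configuration, for provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def mechanics_from_config(cfg: dict) -> MembraneMechanics:
    m = cfg["mechanics"]
    return MembraneMechanics(
        kappa_kbt=m["kappa_kBT"],
        alpha=m["alpha"],
        c0_per_nm=m["c0_per_nm"],
        thickness_nm=m["thickness_nm"],
        delta_a0_nm2=m["delta_a0_nm2"],
        temperature_k=m["temperature_K"],
    )


def designs_from_config(cfg: dict) -> dict[str, ScaffoldDesign]:
    designs = {}
    for name, s in cfg["scaffolds"].items():
        designs[name] = ScaffoldDesign(
            name=name,
            arc_length_nm=s.get("arc_length_nm", 110.0),
            curvature_angle_deg=s.get("angle_deg"),
            radius_nm=s.get("radius_nm"),
            footprint_nm2=s.get("footprint_nm2", 1800.0),
            n_anchors=s.get("n_anchors", 0),
            anchor_face=s.get("anchor_face", "none"),
        )
    return designs
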