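"""End-to-end analysis: simulate or load tables, fit binding and FCS,
convert to densities, evaluate bending energetics, and report the
adhesion-vs-bending decision and morphology statistics per condition.

The composition mirrors how the underlying quantities combine: the fitted
Kd gives the adhesion free energy dG = ln(Kd/1M) kBT of one bound
scaffold; the scaffold's measured radius gives the ADE cost 2*kappa*A/R^2
of bending its membrane footprint into the tube it templates; tubulation
is predicted to be permitted when |dG| >= E_bend.  FCS-fitted particle
numbers become absolute surface densities, extended into the crowded
regime by the intensity calibration, and the morphology table locates the
density threshold at which most vesicles tubulate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .config import (
    config_hash,
    designs_from_config,
    load_config,
    mechanics_from_config,
    resolve_config,
)
from .energetics import adhesion_free_energy, cost_benefit, tube_bending_energy
from .fcs import (
    DetectionVolume,
    build_intensity_calibration,
    fit_fcs,
    load_fcs_curves,
    surface_density,
)
from .geometry import predicted_tube_diameter
from .isotherm import fit_langmuir, load_binding
from .morphology import (
    ThresholdNotReached,
    load_morphology,
    morphology_fractions,
    threshold_density,
)
from .simulate import (
    BindingSimConfig,
    FCSSimConfig,
    MorphologySimConfig,
    gen_binding_dataset,
    gen_fcs_curve,
    gen_morphology_dataset,
)

__all__ = ["RunReport", "run_pipeline", "DILUTION_SCALES"]

#: Particle-number scales (relative to the configured true N) of the
#: simulated FCS dilution series; chosen so roughly half the curves fall in
#: the valid density regime and half in the crowded regime.
DILUTION_SCALES = (0.04, 0.08, 0.12, 0.16, 0.3, 0.6, 1.0, 1.5)

log = logging.getLogger("memscaffold.pipeline")


@dataclass
class RunReport:
    """Machine-readable result of one pipeline run."""

    conditions: dict[str, dict[str, Any]]
    fcs: dict[str, Any]
    morphology: dict[str, Any]
    provenance: dict[str, Any]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _binding_stage(cfg: dict, input_dir: Optional[Path], seed: int) -> dict[str, dict]:
    sim = cfg["simulation"]["binding"]
    out: dict[str, dict] = {}
    if input_dir is not None:
        dataset = load_binding(input_dir / "binding.csv")
        conditions = sorted(dataset.data["condition"].unique())
        per_condition = {c: dataset.for_condition(c) for c in conditions}
    else:
        per_condition = {}
        for i, (name, scaf) in enumerate(cfg["scaffolds"].items()):
            bc = BindingSimConfig(
                true_kd_nm=scaf["kd_nm"],
                true_imax=sim["true_imax"],
                concentrations_nm=tuple(sim["concentrations_nM"]),
                n_guvs_per_conc=sim["n_guvs_per_conc"],
                intensity_cv=sim["intensity_cv"],
                condition=name,
            )
            per_condition[name] = gen_binding_dataset(bc, seed=seed + 101 + i)
    for name, ds in per_condition.items():
        log.info("[binding] fitting condition %s (%d GUVs)", name, len(ds.data))
        fit = fit_langmuir(ds, pooled=cfg["fitting"]["pooled"])
        out[name] = {
            "kd_nM": fit.kd_nm,
            "kd_sd_nM": fit.kd_sd,
            "imax_au": fit.imax,
            "n_guvs": fit.n_guvs,
            "residual_norm": fit.residual_norm,
        }
    return out


def _energetics_stage(cfg: dict, binding: dict[str, dict]) -> dict[str, dict]:
    mech = mechanics_from_config(cfg)
    designs = designs_from_config(cfg)
    out: dict[str, dict] = {}
    for name, fit in binding.items():
        design = designs.get(name)
        entry: dict[str, Any] = {}
        adhesion = adhesion_free_energy(fit["kd_nM"] * 1e-9, mech.temperature_k)
        entry["delta_g_kbt"] = adhesion.delta_g_kbt
        if design is None:
            out[name] = entry
            continue
        entry["curvature_per_um"] = design.curvature_per_um
        if design.is_flat:
            # A flat scaffold templates no tube: zero bending cost but also
            # no predicted tubulation, so the decision is out of scope.
            entry["bending_kbt"] = 0.0
            entry["tube_diameter_nm"] = None
            entry["decision"] = None
        else:
            bend = tube_bending_energy(design.footprint_nm2, design.radius_nm, mech)
            verdict = cost_benefit(adhesion, bend)
            entry["bending_kbt"] = bend
            entry["tube_diameter_nm"] = predicted_tube_diameter(design, round_to_nm=10)
            entry["decision"] = {
                "permitted": verdict.permitted,
                "margin_kbt": verdict.margin_kbt,
            }
        out[name] = entry
    return out


def _fcs_stage(cfg: dict, input_dir: Optional[Path], seed: int) -> dict[str, Any]:
    fcfg = cfg["fcs"]
    vol = DetectionVolume(
        r0_nm=fcfg["r0_nm"], r0_sd_nm=fcfg["r0_sd_nm"], dye=fcfg["dye"],
        d_ref_um2_s=fcfg["d_ref_um2_s"], temperature_k=fcfg["d_ref_temperature_K"],
    )
    length = fcfg["scaffold_length_nm"]
    if input_dir is not None:
        curves = load_fcs_curves(input_dir / "fcs.csv")
    else:
        sim = cfg["simulation"]["fcs"]
        base = FCSSimConfig(
            true_n=sim["true_n"], true_tau_d_s=sim["true_tau_d_s"],
            noise_sd=sim["noise_sd"], lag_min_s=sim["lag_min_s"],
            lag_decades=sim["lag_decades"],
            points_per_decade=sim["points_per_decade"],
        )
        # A dilution series of curves: the low-N end sits in the valid
        # (rho <= 0.2) regime needed to anchor the intensity calibration,
        # the high-N end in the crowded regime it extrapolates to.
        scales = DILUTION_SCALES
        curves = [
            gen_fcs_curve(dataclasses.replace(base, true_n=base.true_n * s),
                          seed=seed + 211 + i, curve_id=f"sim{i}")
            for i, s in enumerate(scales)
        ]
    results = []
    pairs = []
    for curve in curves:
        fit = fit_fcs(curve)
        dens = surface_density(fit, vol, scaffold_length_nm=length)
        # Intensity proxy: proportional to particle number (arbitrary gain).
        intensity = fit.n_particles * 10.0
        pairs.append((intensity, dens))
        results.append(
            {
                "curve_id": curve.curve_id,
                "n_particles": fit.n_particles,
                "tau_d_s": fit.tau_d_s,
                "sigma_per_um2": dens.sigma_per_um2,
                "rho": dens.rho,
                "valid": dens.valid,
            }
        )
    stage: dict[str, Any] = {"curves": results, "r0_nm": vol.r0_nm}
    n_valid = sum(1 for _, d in pairs if d.valid)
    if n_valid >= 3:
        cal = build_intensity_calibration(pairs)
        stage["calibration"] = dataclasses.asdict(cal)
    else:
        log.info("[fcs] only %d valid-regime curves; skipping calibration", n_valid)
        stage["calibration"] = None
    return stage


def _morphology_stage(cfg: dict, input_dir: Optional[Path], seed: int) -> dict[str, Any]:
    if input_dir is not None:
        observations = load_morphology(input_dir / "morphology.csv")
    else:
        sim = cfg["simulation"]["morphology"]
        mcfg = MorphologySimConfig(
            sigma50_per_um2=sim["sigma50_per_um2"], hill_slope=sim["hill_slope"]
        )
        observations = []
        for i, dens in enumerate(sim["densities_per_um2"]):
            observations.extend(
                gen_morphology_dataset(
                    [dens] * sim["n_guvs_per_density"], mcfg,
                    seed=seed + 307 + i, condition=f"sigma={dens}",
                )
            )
    table = morphology_fractions(observations, ci_level=cfg["fitting"]["ci_level"])
    # Tubulated fraction vs density, for threshold extraction.
    points = []
    by_density: dict[float, list] = {}
    for o in observations:
        if o.density_per_um2 is not None:
            by_density.setdefault(o.density_per_um2, []).append(o)
    for dens, group in sorted(by_density.items()):
        frac = sum(1 for o in group if o.morphology == "outward_tubules") / len(group)
        points.append((dens, frac))
    thresholds = {}
    for target in cfg["fitting"]["tubulation_targets"]:
        try:
            thresholds[str(target)] = threshold_density(points, target) if len(points) >= 2 else None
        except ThresholdNotReached as err:
            thresholds[str(target)] = {"not_reached": True, "max_fraction": err.max_fraction}
    return {
        "fractions": table.table.to_dict(orient="records"),
        "tubulation_response": points,
        "threshold_density_per_um2": thresholds,
    }


def run_pipeline(
    config: str | Path | dict | None = None,
    input_dir: str | Path | None = None,
    simulate: bool = False,
    out_path: str | Path | None = None,
) -> RunReport:
    """Run every stage and assemble a :class:`RunReport`.

    Parameters
    ----------
    config
        Path to a YAML config, an overrides dict, or None for defaults.
    input_dir
        Directory holding binding.csv, fcs.csv and morphology.csv.  Mutually
        exclusive with ``simulate``.
    simulate
        Generate all inputs synthetically from the config's simulation
        section (the default when no input_dir is given).
    out_path
        Optional path for the JSON report.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = resolve_config(config)
    if input_dir is not None and simulate:
        raise ValueError("pass either input_dir or simulate=True, not both")
    if input_dir is None:
        simulate = True
    in_dir = None if simulate else Path(input_dir)
    if in_dir is not None and not any(
        (in_dir / f).exists() for f in ("binding.csv", "fcs.csv", "morphology.csv")
    ):
        raise FileNotFoundError(
            f"input directory {in_dir} contains none of binding.csv / fcs.csv / "
            "morphology.csv"
        )
    seed = int(cfg["simulation"]["seed"])

    binding = _binding_stage(cfg, in_dir, seed)
    energetics = _energetics_stage(cfg, binding)
    conditions = {
        name: {"binding": binding[name], **energetics.get(name, {})}
        for name in binding
    }
    fcs_stage = _fcs_stage(cfg, in_dir, seed)
    morph_stage = _morphology_stage(cfg, in_dir, seed)

    report = RunReport(
        conditions=conditions,
        fcs=fcs_stage,
        morphology=morph_stage,
        provenance={
            "config_hash": config_hash(cfg),
            "seed": seed,
            "version": __version__,
            "mode": "simulate" if in_dir is None else "load",
        },
    )
    if out_path is not None:
        report.to_json(out_path)
    return report
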