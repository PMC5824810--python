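"""Geometry of curved membrane-sculpting nanoscaffolds.

Curved DNA-origami scaffolds that mimic BAR-domain proteins are circular
arcs of fixed contour length ``L`` (110 nm for the designs handled here).
A design is characterised either by its TEM-measured radius of curvature
``R`` or by its curvature angle ``theta`` (the angle subtended by the arc),
which yields an arc-derived radius ``L / theta``.  The two typically
disagree by a few percent; both are kept and the measured radius is the
one used for reported numbers.

All lengths are stored in nm.  Curvature is reported in 1/um, the unit
conventional for membrane-curvature work; the nm -> um conversion happens
only at this reporting boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "ScaffoldDesign",
    "curvature_from_radius",
    "radius_from_arc",
    "predicted_tube_diameter",
    "coverage_fraction",
    "FlatDesignError",
    "load_scaffolds",
    "DEFAULT_DESIGNS",
]

#: nm per um, used at every unit boundary.
NM_PER_UM = 1000.0


class FlatDesignError(ValueError):
    """Raised when a curvature-dependent quantity is requested for a flat design."""


def curvature_from_radius(radius_nm: Optional[float]) -> float:
    """Membrane curvature ``C = 1/R`` in 1/um from a radius in nm.

    ``None`` (or ``inf``) denotes a flat design and maps to curvature 0.

    Parameters
    ----------
    radius_nm
        Radius of curvature in nm, or ``None``/``inf`` for a flat design.

    Returns
    -------
    float
        Curvature in 1/um (e.g. R = 46 nm -> 21.7 per um).
    """
    if radius_nm is None or math.isinf(radius_nm):
        return 0.0
    if not (radius_nm > 0):
        raise ValueError(f"radius must be positive or flat, got {radius_nm!r}")
    return NM_PER_UM / radius_nm


def radius_from_arc(arc_length_nm: float, curvature_angle_deg: float) -> float:
    """Radius ``R = L / theta`` (nm) of an arc of length L subtending theta.

    Flat designs (theta = 0) have no finite radius and must not be routed
    through this function.
    """
    if not (arc_length_nm > 0):
        raise ValueError(f"arc length must be positive, got {arc_length_nm!r}")
    if not (0 < curvature_angle_deg <= 360):
        raise FlatDesignError(
            f"curvature angle must lie in (0, 360] degrees, got {curvature_angle_deg!r}"
        )
    return arc_length_nm / math.radians(curvature_angle_deg)


@dataclass(frozen=True)
class ScaffoldDesign:
    """One curved (or flat) nanoscaffold design.

    ``radius_nm`` is the TEM-measured radius of curvature and is the value
    used for reported quantities (tube diameter, curvature).  The
    arc-derived radius ``L/theta`` is exposed separately because the two
    disagree by ~3-5% for the designs studied; which convention produced a
    given printed curvature is recorded per quantity, not guessed.
    """

    name: str
    arc_length_nm: float = 110.0
    curvature_angle_deg: Optional[float] = None
    radius_nm: Optional[float] = None
    footprint_nm2: float = 1800.0
    n_anchors: int = 0
    anchor_face: str = "none"

    def __post_init__(self) -> None:
        if not (self.arc_length_nm > 0):
            raise ValueError("arc_length_nm must be positive")
        if not (self.footprint_nm2 > 0):
            raise ValueError("footprint_nm2 must be positive")
        if self.n_anchors < 0:
            raise ValueError("n_anchors must be non-negative")
        if self.anchor_face not in {"concave", "convex", "lateral", "none"}:
            raise ValueError(f"unknown anchor_face {self.anchor_face!r}")
        if self.radius_nm is not None and not (self.radius_nm > 0):
            raise ValueError("radius_nm must be positive when present")

    @property
    def is_flat(self) -> bool:
        return self.radius_nm is None and self.curvature_angle_deg is None

    @property
    def curvature_per_um(self) -> float:
        """Curvature 1/R in 1/um from the measured radius; 0 for flat designs."""
        return curvature_from_radius(self.radius_nm)

    @property
    def arc_radius_nm(self) -> Optional[float]:
        """Radius implied by the arc geometry L/theta; None for flat designs."""
        if self.curvature_angle_deg is None:
            return None
        return radius_from_arc(self.arc_length_nm, self.curvature_angle_deg)

    @property
    def arc_curvature_per_um(self) -> float:
        """Curvature theta/L implied by the arc geometry; 0 for flat designs."""
        r = self.arc_radius_nm
        return 0.0 if r is None else NM_PER_UM / r


def predicted_tube_diameter(design: ScaffoldDesign, round_to_nm: float = 0.0) -> float:
    """Diameter ``2R`` (nm) of the membrane tube a curved scaffold templates.

    A scaffold of radius R wrapped around a cylinder predicts a tube of the
    same radius, i.e. diameter 2R (84 nm -> 168 nm, ~170 at 10-nm rounding).

    Parameters
    ----------
    design
        Scaffold design; must carry a measured radius.
    round_to_nm
        Optional reporting grid (e.g. 10 to match "~170 nm" style figures);
        0 disables rounding.
    """
    if design.radius_nm is None:
        raise FlatDesignError(
            f"design {design.name!r} is flat: no finite tube diameter is predicted"
        )
    d = 2.0 * design.radius_nm
    if round_to_nm:
        d = round(d / round_to_nm) * round_to_nm
    return d


def coverage_fraction(surface_density_per_um2: float, footprint_nm2: float) -> float:
    """Fraction of membrane area covered: ``sigma * A`` (dimensionless).

    ``sigma`` is the particle surface density in 1/um^2 and ``A`` the
    per-particle footprint in nm^2; e.g. 50 /um^2 x 1800 nm^2 = 0.09 (9%).
    """
    if surface_density_per_um2 < 0:
        raise ValueError("surface density must be non-negative")
    if footprint_nm2 < 0:
        raise ValueError("footprint area must be non-negative")
    return surface_density_per_um2 * footprint_nm2 / NM_PER_UM**2


# The three study designs: a half-circle (H), a quarter-circle (Q) and a
# straight rod (L), all 110 nm long with an ~1800 nm^2 membrane footprint.
DEFAULT_DESIGNS: dict[str, ScaffoldDesign] = {
    "H": ScaffoldDesign(
        name="H", curvature_angle_deg=131.0, radius_nm=46.0,
        n_anchors=3, anchor_face="concave",
    ),
    "Q": ScaffoldDesign(
        name="Q", curvature_angle_deg=73.0, radius_nm=84.0,
        n_anchors=3, anchor_face="concave",
    ),
    "L": ScaffoldDesign(name="L", n_anchors=3, anchor_face="concave"),
}


def load_scaffolds(path: str | Path) -> dict[str, ScaffoldDesign]:
    """Read scaffold designs from a CSV table.

    Columns: name, arc_length_nm, angle_deg, radius_nm, curvature_per_um,
    footprint_nm2, n_anchors, anchor_face.  Blank angle/radius mean a flat
    design.  A non-blank curvature_per_um is checked against 1/radius.
    """
    df = pd.read_csv(path)
    designs: dict[str, ScaffoldDesign] = {}
    for _, row in df.iterrows():
        radius = None if pd.isna(row.get("radius_nm")) else float(row["radius_nm"])
        angle = None if pd.isna(row.get("angle_deg")) else float(row["angle_deg"])
        design = ScaffoldDesign(
            name=str(row["name"]),
            arc_length_nm=float(row.get("arc_length_nm", 110.0)),
            curvature_angle_deg=angle,
            radius_nm=radius,
            footprint_nm2=float(row.get("footprint_nm2", 1800.0)),
            n_anchors=int(row.get("n_anchors", 0)),
            anchor_face=str(row.get("anchor_face", "none")),
        )
        stated = row.get("curvature_per_um")
        if stated is not None and not pd.isna(stated):
            derived = design.curvature_per_um
            if abs(float(stated) - derived) > 1e-9 * max(1.0, abs(derived)):
                raise ValueError(
                    f"design {design.name!r}: stated curvature {stated} /um "
                    f"inconsistent with 1/radius = {derived:.6g} /um"
                )
        designs[design.name] = design
    return designs
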