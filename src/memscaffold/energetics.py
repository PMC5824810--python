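"""Area-difference-elasticity (ADE) bending energetics and the
adhesion-versus-bending cost-benefit rule.

The ADE model extends the Helfrich bending energy with a non-local penalty
for the area difference between the two bilayer leaflets:

    E_be = kappa * [ (1/2) Int dA (C1 + C2 - C0)^2
                     + (alpha/2) * (pi / (A D^2)) * (dA - dA0)^2 ]

with kappa the bending modulus, C1/C2 the principal curvatures, C0 the
spontaneous curvature, A the patch area, D the bilayer thickness, dA the
leaflet area difference and alpha = kbar/kappa the ratio of non-local to
local rigidity.  For a membrane patch of area A bent into a cylinder of
radius R (C1 = 1/R, C2 = 0, dA = D*A/R) with C0 = dA0 = 0 and the standard
approximation alpha = 3/pi the energy collapses to the closed form

    E_tube = 2 * kappa * A / R^2,

independent of the bilayer thickness.

Energies are expressed in units of kBT throughout; the adhesion free
energy of a bound scaffold is dG = ln(Kd / 1 M) kBT at the 1 M standard
state, so nanomolar dissociation constants give ~ -20 kBT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "MembraneMechanics",
    "PatchSpec",
    "AdhesionEnergy",
    "CostBenefit",
    "ade_bending_energy",
    "tube_area_difference",
    "tube_bending_energy",
    "adhesion_free_energy",
    "cost_benefit",
]


@dataclass(frozen=True)
class MembraneMechanics:
    """Elastic constants of the bilayer.

    Defaults describe a DOPC bilayer: bending modulus kappa = 23.1 kBT,
    non-local rigidity ratio alpha = 3/pi, no spontaneous curvature, 4 nm
    thickness, relaxed leaflet area difference zero.
    """

    kappa_kbt: float = 23.1
    alpha: float = 3.0 / math.pi
    c0_per_nm: float = 0.0
    thickness_nm: float = 4.0
    delta_a0_nm2: float = 0.0
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if not (self.kappa_kbt > 0):
            raise ValueError("kappa must be positive")
        if not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if not (self.thickness_nm > 0):
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class PatchSpec:
    """A membrane patch of uniform principal curvatures.

    ``delta_a_nm2`` is the leaflet area difference of the deformed patch;
    for a cylindrical tube it can be derived with :func:`tube_area_difference`.
    """

    area_nm2: float
    c1_per_nm: float = 0.0
    c2_per_nm: float = 0.0
    delta_a_nm2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.area_nm2 > 0):
            raise ValueError("patch area must be positive")


@dataclass(frozen=True)
class AdhesionEnergy:
    """Adhesion free energy of one bound scaffold, in kBT, from its Kd."""

    delta_g_kbt: float
    kd_molar: float
    temperature_k: float = 298.15

    def delta_g_joule(self) -> float:
        """Convert to joules using kB*T at the stored temperature."""
        k_b = 1.380649e-23  # J/K
        return self.delta_g_kbt * k_b * self.temperature_k


@dataclass(frozen=True)
class CostBenefit:
    """Outcome of the adhesion-vs-bending comparison for one design."""

    permitted: bool
    margin_kbt: float
    adhesion_kbt: float
    bending_kbt: float


def ade_bending_energy(patch: PatchSpec, mech: MembraneMechanics) -> float:
    """ADE bending energy (kBT) of a uniform-curvature membrane patch.

    For uniform curvatures the local integral reduces to multiplication by
    the patch area.  The leaflet area difference must be supplied on the
    patch; tube callers should use :func:`tube_bending_energy`, which
    derives it from the geometry.
    """
    if patch.delta_a_nm2 is None:
        raise ValueError(
            "patch.delta_a_nm2 is required: supply the leaflet area difference "
            "explicitly or use tube_bending_energy for cylindrical patches"
        )
    local = 0.5 * patch.area_nm2 * (
        patch.c1_per_nm + patch.c2_per_nm - mech.c0_per_nm
    ) ** 2
    nonlocal_ = (
        0.5
        * mech.alpha
        * math.pi
        / (patch.area_nm2 * mech.thickness_nm**2)
        * (patch.delta_a_nm2 - mech.delta_a0_nm2) ** 2
    )
    return mech.kappa_kbt * (local + nonlocal_)


def tube_area_difference(area_nm2: float, radius_nm: float, thickness_nm: float) -> float:
    """Leaflet area difference ``dA = D*A/R`` (nm^2) for a cylindrical patch.

    The two leaflets are separated by the bilayer thickness D; on a cylinder
    of radius R the outer leaflet exceeds the inner by D*A/R.  A flat patch
    (infinite radius) has dA = 0.
    """
    if not (area_nm2 > 0):
        raise ValueError("area must be positive")
    if not (thickness_nm > 0):
        raise ValueError("thickness must be positive")
    if math.isinf(radius_nm):
        return 0.0
    if not (radius_nm > 0):
        raise ValueError("radius must be positive or infinite (flat)")
    return thickness_nm * area_nm2 / radius_nm


def tube_bending_energy(
    area_nm2: float, radius_nm: float, mech: MembraneMechanics | None = None
) -> float:
    """Energy (kBT) to bend a flat patch of area A into a tube of radius R.

    Composes :func:`ade_bending_energy` with C1 = 1/R, C2 = 0 and the
    geometric leaflet area difference D*A/R.  With alpha = 3/pi and
    C0 = dA0 = 0 this equals 2*kappa*A/R^2; the bilayer thickness cancels.
    """
    mech = mech or MembraneMechanics()
    if not (radius_nm > 0):
        raise ValueError("radius must be positive")
    patch = PatchSpec(
        area_nm2=area_nm2,
        c1_per_nm=1.0 / radius_nm,
        c2_per_nm=0.0,
        delta_a_nm2=tube_area_difference(area_nm2, radius_nm, mech.thickness_nm),
    )
    return ade_bending_energy(patch, mech)


def adhesion_free_energy(
    kd_molar: float, temperature_k: float = 298.15
) -> AdhesionEnergy:
    """Adhesion free energy dG = ln(Kd / 1 M) in kBT at the 1 M standard state.

    In kBT units the temperature enters only when converting to joules
    (see :meth:`AdhesionEnergy.delta_g_joule`).
    """
    if not (kd_molar > 0):
        raise ValueError(f"Kd must be positive, got {kd_molar!r}")
    return AdhesionEnergy(
        delta_g_kbt=math.log(kd_molar),
        kd_molar=kd_molar,
        temperature_k=temperature_k,
    )


def cost_benefit(adhesion: AdhesionEnergy, bending_kbt: float) -> CostBenefit:
    """Decide whether adhesion can pay for bending.

    Tubulation is energetically permitted when the magnitude of the adhesion
    free energy matches or exceeds the bending cost; equality counts as
    permitted.  The margin is |dG| - E_bend (positive when permitted).
    """
    if bending_kbt < 0:
        raise ValueError("bending energy must be non-negative")
    gain = abs(adhesion.delta_g_kbt)
    return CostBenefit(
        permitted=gain >= bending_kbt,
        margin_kbt=gain - bending_kbt,
        adhesion_kbt=adhesion.delta_g_kbt,
        bending_kbt=bending_kbt,
    )
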