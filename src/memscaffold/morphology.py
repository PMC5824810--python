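"""Per-GUV morphology statistics: deformation fractions, density thresholds
for tubulation, and tube-diameter summaries.

Each giant unilamellar vesicle (GUV) in an experiment is classified into
one morphology category (spherical, outward tubules, inward tubules,
evagination/invagination, flaccid, burst).  Per condition the category
fractions are reported with Wilson score confidence intervals, which stay
sensible at the small n typical of GUV counting.

The density threshold for tubulation is read off the (surface density,
tubulated fraction) response: the smallest density whose interpolated
fraction reaches a target, after isotonic smoothing so experimental
non-monotonicity cannot produce spurious crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MORPHOLOGIES",
    "GUVObservation",
    "MorphologyTable",
    "morphology_fractions",
    "threshold_density",
    "ThresholdNotReached",
    "summarize_tube_diameters",
    "load_morphology",
]

#: Closed vocabulary of per-GUV outcomes; labels are case-normalised on input.
MORPHOLOGIES = (
    "spherical",
    "outward_tubules",
    "inward_tubules",
    "evagination_invagination",
    "flaccid",
    "burst",
)


@dataclass(frozen=True)
class GUVObservation:
    """One vesicle's outcome under one condition.

    ``density_per_um2`` is the scaffold surface density when known (FCS or
    intensity-calibrated); burst vesicles count towards condition totals.
    """

    guv_id: str
    condition: str
    morphology: str
    density_per_um2: Optional[float] = None

    def __post_init__(self) -> None:
        morph = self.morphology.strip().lower()
        object.__setattr__(self, "morphology", morph)
        if morph not in MORPHOLOGIES:
            raise ValueError(
                f"unknown morphology {self.morphology!r}; "
                f"expected one of {MORPHOLOGIES}"
            )
        if self.density_per_um2 is not None and self.density_per_um2 < 0:
            raise ValueError("density must be non-negative when present")


@dataclass(frozen=True)
class MorphologyTable:
    """Per-(condition, morphology) counts, fractions and Wilson CIs.

    ``table`` columns: condition, morphology, count, n, fraction, ci_low,
    ci_high.  Fractions over morphologies sum to 1 within each condition.
    """

    table: pd.DataFrame
    ci_level: float = 0.95

    def fraction(self, condition: str, morphology: str) -> float:
        sel = self.table[
            (self.table["condition"] == condition)
            & (self.table["morphology"] == morphology)
        ]
        return float(sel["fraction"].iloc[0]) if not sel.empty else 0.0


def morphology_fractions(
    observations: Iterable[GUVObservation], ci_level: float = 0.95
) -> MorphologyTable:
    """Aggregate per-GUV calls into per-condition fractions with Wilson CIs.

    Every category in the vocabulary is reported for every condition
    (zero counts included) so fractions always sum to one.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    df = pd.DataFrame(
        {
            "condition": [o.condition for o in obs],
            "morphology": [o.morphology for o in obs],
        }
    )
    rows = []
    for condition, sub in df.groupby("condition", sort=False):
        n = len(sub)
        counts = sub["morphology"].value_counts()
        for morph in MORPHOLOGIES:
            k = int(counts.get(morph, 0))
            lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
            rows.append(
                {
                    "condition": condition,
                    "morphology": morph,
                    "count": k,
                    "n": n,
                    "fraction": k / n,
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return MorphologyTable(table=pd.DataFrame(rows), ci_level=ci_level)


class ThresholdNotReached(ValueError):
    """The tubulated fraction never reaches the requested target."""

    def __init__(self, target: float, max_fraction: float):
        self.target = target
        self.max_fraction = max_fraction
        super().__init__(
            f"target fraction {target} never reached "
            f"(maximum observed {max_fraction:.3f})"
        )


def threshold_density(
    points: Sequence[tuple[float, float]], target_fraction: float
) -> float:
    """Smallest surface density at which the tubulated fraction reaches a target.

    The (density, fraction) response is first made monotone by isotonic
    regression (least-squares nearest non-decreasing fit; a no-op on
    already-monotone data), then the crossing is located by linear
    interpolation between the bracketing points.

    Raises
    ------
    ThresholdNotReached
        If even the smoothed maximum fraction stays below the target.
    """
    pts = sorted(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 (density, fraction) points")
    dens = np.array([p[0] for p in pts], dtype=float)
    frac = np.array([p[1] for p in pts], dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    if not (0 <= target_fraction <= 1):
        raise ValueError("target fraction must lie in [0, 1]")

    frac = IsotonicRegression(increasing=True).fit_transform(dens, frac)

    if target_fraction <= frac[0]:
        return float(dens[0])
    if frac.max() < target_fraction:
        raise ThresholdNotReached(target_fraction, float(frac.max()))
    idx = int(np.argmax(frac >= target_fraction))
    d0, d1 = dens[idx - 1], dens[idx]
    f0, f1 = frac[idx - 1], frac[idx]
    if f1 == f0:
        return float(d1)
    return float(d0 + (target_fraction - f0) * (d1 - d0) / (f1 - f0))


def summarize_tube_diameters(
    cross_sections_nm: Sequence[float], predicted_nm: float
) -> dict:
    """Mean +/- s.d. of measured tube cross-sections vs the geometric prediction.

    Returns mean, sd (ddof=1), n, the predicted diameter and the
    measured/predicted ratio.
    """
    x = np.asarray(cross_sections_nm, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cross-sections")
    mean = float(x.mean())
    return {
        "mean_nm": mean,
        "sd_nm": float(x.std(ddof=1)),
        "n": int(x.size),
        "predicted_nm": float(predicted_nm),
        "ratio": mean / predicted_nm,
    }


def load_morphology(path: str | Path) -> list[GUVObservation]:
    """Read per-GUV outcomes from a CSV (guv_id, condition, density_per_um2, morphology)."""
    df = pd.read_csv(path)
    obs = []
    for _, row in df.iterrows():
        dens = row.get("density_per_um2")
        obs.append(
            GUVObservation(
                guv_id=str(row["guv_id"]),
                condition=str(row["condition"]),
                morphology=str(row["morphology"]),
                density_per_um2=None if pd.isna(dens) else float(dens),
            )
        )
    return obs
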