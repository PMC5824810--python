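"""Langmuir binding-isotherm fitting for per-GUV titration data.

Membrane-bound fluorescence intensity I of a scaffold at equilibrium as a
function of its bulk concentration follows the Langmuir isotherm

    I = Imax / (1 + Kd / Cbulk),

with Kd the apparent dissociation constant (the bulk concentration at
half-maximal coverage) and Imax the saturation intensity.  Fitting is
ordinary least squares on raw intensities, parameterised in
(log Kd, log Imax) so positivity is structural; standard errors are
delta-method transforms of the Jacobian-based covariance.

Independent titration repeats are fit separately and summarised as
mean +/- s.d. of Kd across repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "BindingDataset",
    "LangmuirFit",
    "langmuir_model",
    "fit_langmuir",
    "fit_repeats",
    "load_binding",
]


def langmuir_model(bulk_conc_nm, kd_nm: float, imax: float):
    """Langmuir isotherm ``Imax / (1 + Kd/Cbulk)``.

    Vectorised over ``bulk_conc_nm``; the Cbulk -> 0 limit is 0 and
    Cbulk -> inf saturates at Imax.
    """
    if not (kd_nm > 0) or not (imax > 0):
        raise ValueError("Kd and Imax must be positive")
    c = np.asarray(bulk_conc_nm, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.where(c > 0, imax / (1.0 + kd_nm / np.where(c > 0, c, 1.0)), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BindingDataset:
    """Per-GUV intensities vs bulk concentration for one condition.

    ``data`` columns: guv_id, condition, repeat (optional), bulk_conc_nM,
    intensity_au.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"bulk_conc_nM", "intensity_au"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"binding table is missing columns {sorted(missing)}")
        if (self.data["bulk_conc_nM"] <= 0).any():
            raise ValueError("bulk concentrations must be positive")
        if (self.data["intensity_au"] < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["bulk_conc_nM"].unique())

    def for_condition(self, condition: str) -> "BindingDataset":
        sub = self.data[self.data["condition"] == condition]
        if sub.empty:
            raise ValueError(f"no records for condition {condition!r}")
        return BindingDataset(sub.reset_index(drop=True))


@dataclass(frozen=True)
class LangmuirFit:
    """Fitted Langmuir parameters with delta-method standard errors."""

    kd_nm: float
    imax: float
    kd_sd: float
    imax_sd: float
    n_guvs: int
    residual_norm: float
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, bulk_conc_nm):
        return langmuir_model(bulk_conc_nm, self.kd_nm, self.imax)


def _initial_guess(conc: np.ndarray, intensity: np.ndarray) -> tuple[float, float]:
    # Imax from the bright tail; Kd from the concentration nearest half of it.
    imax0 = max(np.percentile(intensity, 95), 1e-12)
    half_gap = np.abs(intensity - imax0 / 2.0)
    kd0 = max(conc[np.argmin(half_gap)], 1e-12)
    return kd0, imax0


def fit_langmuir(
    dataset: BindingDataset | pd.DataFrame,
    pooled: bool = True,
) -> LangmuirFit:
    """Fit the Langmuir isotherm to a binding titration.

    Parameters
    ----------
    dataset
        Per-GUV records (or a raw DataFrame with the same columns).
    pooled
        If True (default), fit all per-GUV points together.  If False,
        per-concentration mean intensities are fit instead.

    Returns
    -------
    LangmuirFit
        Kd (nM), Imax and their standard errors, with per-point residuals.
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = BindingDataset(dataset)
    df = dataset.data
    if not pooled:
        df = (
            df.groupby("bulk_conc_nM", as_index=False)["intensity_au"]
            .mean()
        )
    conc = df["bulk_conc_nM"].to_numpy(dtype=float)
    intensity = df["intensity_au"].to_numpy(dtype=float)

    distinct = np.unique(conc)
    if distinct.size < 2:
        raise ValueError(
            "fitting needs at least 2 distinct concentrations "
            f"(got {distinct.size}); the isotherm is not identifiable"
        )
    if distinct.max() / distinct.min() < 4:
        warnings.warn(
            "concentration range spans less than 4-fold; Kd may be poorly "
            "constrained",
            stacklevel=2,
        )
    if np.all(intensity == 0):
        raise ValueError("all intensities are zero; nothing to fit")

    kd0, imax0 = _initial_guess(conc, intensity)
    theta0 = np.log([kd0, imax0])

    def residual(theta: np.ndarray) -> np.ndarray:
        kd, imax = np.exp(theta)
        return langmuir_model(conc, kd, imax) - intensity

    sol = least_squares(residual, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"Langmuir fit failed: {sol.message}")
    kd, imax = np.exp(sol.x)

    # Covariance of log-parameters from the Jacobian; delta method maps the
    # SD of log(p) onto p as sd(p) = p * sd(log p).
    dof = max(conc.size - 2, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        log_sd = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        log_sd = np.full(2, np.nan)

    return LangmuirFit(
        kd_nm=float(kd),
        imax=float(imax),
        kd_sd=float(kd * log_sd[0]),
        imax_sd=float(imax * log_sd[1]),
        n_guvs=int(conc.size),
        residual_norm=float(np.linalg.norm(sol.fun)),
        residuals=sol.fun.copy(),
    )


def fit_repeats(dataset: BindingDataset) -> dict:
    """Fit each independent titration repeat separately and summarise.

    Returns a dict with the per-repeat fits and the mean +/- s.d. of Kd
    across repeats (s.d. is NaN with a single repeat).
    """
    df = dataset.data
    if "repeat" not in df.columns:
        fits = [fit_langmuir(dataset)]
    else:
        fits = [
            fit_langmuir(BindingDataset(sub.reset_index(drop=True)))
            for _, sub in df.groupby("repeat")
        ]
    kds = np.array([f.kd_nm for f in fits])
    return {
        "fits": fits,
        "kd_mean_nm": float(kds.mean()),
        "kd_sd_nm": float(kds.std(ddof=1)) if kds.size > 1 else float("nan"),
        "n_repeats": len(fits),
    }


def load_binding(path: str | Path) -> BindingDataset:
    """Read a binding titration CSV (guv_id, condition, repeat, bulk_conc_nM, intensity_au)."""
    return BindingDataset(pd.read_csv(path))
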