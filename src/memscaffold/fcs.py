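"""Fluorescence correlation spectroscopy on membranes: one-component 2D
diffusion model, detection-volume calibration and absolute surface density.

For particles diffusing in a membrane plane through a Gaussian detection
spot, the autocorrelation of the fluorescence signal is

    G(tau) = (1/N) * 1 / (1 + tau/tau_D),

where N is the mean particle number inside the 2D detection area and
tau_D = r0^2 / (4 D) the diffusion time through the spot of waist radius
r0.  Fitting a measured curve yields N and tau_D; with a calibrated r0 the
absolute surface density follows as sigma = N / (pi r0^2).

The dimensionless reduced density rho = sigma * L^2 (L the scaffold
length) flags the crowding regime: above rho = 0.2 the one-component model
misdescribes the curves, and densities there must instead come from a
linear fluorescence-intensity calibration built in the valid regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

__all__ = [
    "AutocorrelationCurve",
    "FCSFit",
    "DetectionVolume",
    "DensityEstimate",
    "DensityCalibration",
    "fcs_model_2d",
    "fit_fcs",
    "waist_from_reference",
    "diffusion_time",
    "temperature_correct_d",
    "water_viscosity_mpa_s",
    "surface_density",
    "build_intensity_calibration",
    "density_from_intensity",
    "load_fcs_curves",
]

RHO_CROWDING = 0.2  # reduced density above which FCS fits are untrusted


def fcs_model_2d(lag_s, n_particles: float, tau_d_s: float):
    """Autocorrelation ``G(tau) = (1/N) / (1 + tau/tau_D)`` for 2D diffusion.

    Vectorised over ``lag_s``.  G(0) = 1/N is the amplitude and
    G(tau_D) = 1/(2N) defines the half-decay.
    """
    if not (n_particles > 0):
        raise ValueError("N must be positive")
    if not (tau_d_s > 0):
        raise ValueError("tau_D must be positive")
    tau = np.asarray(lag_s, dtype=float)
    if (tau < 0).any():
        raise ValueError("lags must be non-negative")
    out = (1.0 / n_particles) / (1.0 + tau / tau_d_s)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AutocorrelationCurve:
    """One measured (or simulated) autocorrelation curve."""

    lags_s: np.ndarray
    g: np.ndarray
    curve_id: str = ""

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags_s, dtype=float)
        g = np.asarray(self.g, dtype=float)
        object.__setattr__(self, "lags_s", lags)
        object.__setattr__(self, "g", g)
        if lags.shape != g.shape or lags.ndim != 1:
            raise ValueError("lags and g must be 1-D arrays of equal length")
        if lags.size < 10:
            raise ValueError("need at least 10 lag points to fit")
        if (lags <= 0).any() or (np.diff(lags) <= 0).any():
            raise ValueError("lags must be positive and strictly increasing")
        if lags[-1] / lags[0] < 1e3:
            warnings.warn(
                "lag grid spans fewer than 3 decades; tau_D may be poorly "
                "constrained",
                stacklevel=2,
            )


@dataclass(frozen=True)
class FCSFit:
    """Fitted particle number and diffusion time with standard errors."""

    n_particles: float
    tau_d_s: float
    n_sd: float
    tau_d_sd: float
    residual_norm: float


@dataclass(frozen=True)
class DetectionVolume:
    """Lateral waist of the confocal detection spot, from dye calibration."""

    r0_nm: float
    r0_sd_nm: float = 0.0
    dye: str = ""
    d_ref_um2_s: float = float("nan")
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if not (self.r0_nm > 0):
            raise ValueError("waist radius must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * (self.r0_nm / 1000.0) ** 2


@dataclass(frozen=True)
class DensityEstimate:
    """Absolute and reduced surface density of membrane-bound particles.

    ``valid`` is False in the crowding regime (rho > 0.2), where the FCS
    model itself is unreliable; ``source`` records whether the estimate came
    from an FCS fit or from the intensity calibration.
    """

    sigma_per_um2: float
    rho: float
    valid: bool
    source: str = "fcs"

    def __post_init__(self) -> None:
        if self.sigma_per_um2 < 0:
            raise ValueError("sigma must be non-negative")
        if self.source not in {"fcs", "intensity_calibration"}:
            raise ValueError(f"unknown source {self.source!r}")


def fit_fcs(curve: AutocorrelationCurve) -> FCSFit:
    """Least-squares fit of the one-component 2D model to a curve.

    Initialisation: N from the amplitude at the shortest lag, tau_D from the
    lag nearest half that amplitude.  The fit minimises unweighted residuals
    in G over the (log-spaced) lag grid, parameterised in
    (log N, log tau_D) for positivity.
    """
    g = curve.g
    if g[0] <= 0:
        raise ValueError("non-positive correlation amplitude; cannot fit")
    g0 = g[0]
    half_idx = int(np.argmin(np.abs(g - g0 / 2.0)))
    tau_half = curve.lags_s[half_idx]
    if g[half_idx] > 0.75 * g0:
        # Curve never decays towards half amplitude within the grid.
        raise ValueError(
            "correlation curve does not decay over the measured lags; "
            "tau_D is unidentifiable (constant curve?)"
        )
    theta0 = np.log([1.0 / g0, tau_half])

    def residual(theta: np.ndarray) -> np.ndarray:
        n, tau_d = np.exp(theta)
        return fcs_model_2d(curve.lags_s, n, tau_d) - g

    sol = least_squares(residual, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"FCS fit failed: {sol.message}")
    n, tau_d = np.exp(sol.x)

    dof = max(g.size - 2, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        log_sd = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        log_sd = np.full(2, np.nan)

    return FCSFit(
        n_particles=float(n),
        tau_d_s=float(tau_d),
        n_sd=float(n * log_sd[0]),
        tau_d_sd=float(tau_d * log_sd[1]),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def waist_from_reference(tau_d_ref_s: float, d_ref_um2_s: float) -> float:
    """Waist radius r0 (nm) from a reference dye: ``r0 = sqrt(4 D tau_D)``.

    The dye's known diffusion coefficient D (um^2/s) and its fitted
    diffusion time through the spot calibrate the detection area.
    """
    if not (tau_d_ref_s > 0) or not (d_ref_um2_s > 0):
        raise ValueError("tau_D and D must be positive")
    r0_um = math.sqrt(4.0 * d_ref_um2_s * tau_d_ref_s)
    return r0_um * 1000.0


def diffusion_time(r0_nm: float, d_um2_s: float) -> float:
    """Diffusion time ``tau_D = r0^2 / (4 D)`` in seconds."""
    if not (r0_nm > 0) or not (d_um2_s > 0):
        raise ValueError("r0 and D must be positive")
    return (r0_nm / 1000.0) ** 2 / (4.0 * d_um2_s)


def water_viscosity_mpa_s(temperature_k: float) -> float:
    """Dynamic viscosity of water (mPa s) between 15 and 40 degrees C.

    Standard empirical (Vogel-type) correlation
    ``eta = 2.414e-2 * 10^(247.8 / (T - 140))`` mPa s, accurate to ~0.3%
    against reference tables in this range (0.8906 at 25 C).
    """
    if not (288.15 <= temperature_k <= 313.15):
        raise ValueError(
            f"temperature {temperature_k} K outside supported range 15-40 C"
        )
    return 2.414e-2 * 10.0 ** (247.8 / (temperature_k - 140.0))


def temperature_correct_d(
    d_ref_um2_s: float, t_ref_k: float, t_work_k: float
) -> float:
    """Stokes-Einstein temperature correction of a diffusion coefficient.

    ``D2 = D1 * (T2/T1) * (eta(T1)/eta(T2))`` with the water viscosity
    correlation above.  Used to carry a dye's tabulated D (e.g. at 25 C) to
    the working temperature at the objective.
    """
    if not (d_ref_um2_s > 0):
        raise ValueError("D must be positive")
    return (
        d_ref_um2_s
        * (t_work_k / t_ref_k)
        * (water_viscosity_mpa_s(t_ref_k) / water_viscosity_mpa_s(t_work_k))
    )


def surface_density(
    fit: FCSFit | float,
    vol: DetectionVolume,
    scaffold_length_nm: float = 110.0,
) -> DensityEstimate:
    """Absolute surface density ``sigma = N / (pi r0^2)`` and crowding flag.

    Parameters
    ----------
    fit
        An :class:`FCSFit` or a bare particle number N.
    vol
        Calibrated detection volume.
    scaffold_length_nm
        Scaffold length L entering the reduced density rho = sigma L^2.

    Returns
    -------
    DensityEstimate
        sigma in 1/um^2, rho, and valid = (rho <= 0.2).
    """
    n = fit.n_particles if isinstance(fit, FCSFit) else float(fit)
    if n < 0:
        raise ValueError("particle number must be non-negative")
    sigma = n / vol.area_um2
    rho = sigma * (scaffold_length_nm / 1000.0) ** 2
    return DensityEstimate(
        sigma_per_um2=sigma, rho=rho, valid=rho <= RHO_CROWDING, source="fcs"
    )


@dataclass(frozen=True)
class DensityCalibration:
    """Linear intensity -> density calibration fitted in the valid regime."""

    slope: float
    intercept: float
    n_guvs: int
    r_squared: float
    n_excluded: int = 0


def build_intensity_calibration(
    pairs: Iterable[tuple[float, DensityEstimate]],
) -> DensityCalibration:
    """Ordinary least-squares line ``sigma = slope * I + intercept``.

    Only pairs with a valid (non-crowded, rho <= 0.2) FCS density enter the
    fit; excluded pairs are counted.  At least 3 valid pairs are required.
    """
    pairs = list(pairs)
    valid = [(i, d.sigma_per_um2) for i, d in pairs if d.valid]
    n_excluded = len(pairs) - len(valid)
    if len(valid) < 3:
        raise ValueError(
            f"need at least 3 valid-regime (rho <= {RHO_CROWDING}) pairs, "
            f"got {len(valid)} ({n_excluded} excluded as crowded)"
        )
    intensity = np.array([p[0] for p in valid])
    sigma = np.array([p[1] for p in valid])
    res = linregress(intensity, sigma)
    return DensityCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_guvs=len(valid),
        r_squared=float(res.rvalue**2),
        n_excluded=n_excluded,
    )


def density_from_intensity(
    intensity: float,
    calibration: DensityCalibration,
    scaffold_length_nm: float = 110.0,
) -> DensityEstimate:
    """Surface density from fluorescence intensity via the calibration line.

    This is the route for the crowded regime, where the FCS model itself is
    invalid but intensity remains proportional to density.  Negative
    predictions are clipped to zero with a warning.
    """
    sigma = calibration.slope * intensity + calibration.intercept
    if sigma < 0:
        warnings.warn(
            f"calibration predicts negative density ({sigma:.3g}/um^2); "
            "clipping to 0",
            stacklevel=2,
        )
        sigma = 0.0
    rho = sigma * (scaffold_length_nm / 1000.0) ** 2
    return DensityEstimate(
        sigma_per_um2=sigma,
        rho=rho,
        valid=rho <= RHO_CROWDING,
        source="intensity_calibration",
    )


def load_fcs_curves(path: str | Path) -> list[AutocorrelationCurve]:
    """Read autocorrelation curves from a CSV (curve_id, lag_s, g)."""
    df = pd.read_csv(path)
    curves = []
    for cid, sub in df.groupby("curve_id", sort=False):
        sub = sub.sort_values("lag_s")
        curves.append(
            AutocorrelationCurve(
                lags_s=sub["lag_s"].to_numpy(),
                g=sub["g"].to_numpy(),
                curve_id=str(cid),
            )
        )
    return curves
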