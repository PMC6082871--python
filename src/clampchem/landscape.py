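"""Bell/Arrhenius force-dependence fits and titration (pKa) fits.

The force dependence of the concentration-normalized cleavage rate is fitted
as a straight line on the semi-log plot: ln r_norm(F) = ln r0_norm +
F dx / kBT.  The slope gives the distance to the transition state dx, the
intercept the zero-force rate r0_norm, and the activation barrier follows
from the pre-exponential as ln(A / r0_norm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .core import Constants, DEFAULT_CONSTANTS, barrier_from_rate, titration_absorbance
from .kinetics import RateEstimate

__all__ = ["LandscapeFit", "TitrationData", "fit_bell", "fit_pka", "charge_rate_regression"]


@dataclass(frozen=True)
class LandscapeFit:
    """Bell-regression parameters of one compound's force series."""

    dx_A: float
    r0_norm_M_s: float
    dG_barrier_kT: float
    dx_sd_A: float
    r0_sd_M_s: float
    dG_barrier_sd_kT: float
    n_forces: int
    compound_name: str = ""

    def __post_init__(self) -> None:
        if self.dx_A <= 0:
            raise ValueError("fitted dx must be > 0")
        if self.dG_barrier_kT <= 0:
            raise ValueError("fitted barrier must be > 0")
        if self.n_forces < 2:
            raise ValueError("Bell fit needs >= 2 forces")


@dataclass(frozen=True)
class TitrationData:
    """Absorbance-vs-pH record with optional fitted pKa."""

    pH: np.ndarray
    absorbance: np.ndarray
    pKa_fit: float | None = None
    pKa_sd: float | None = None

    def __post_init__(self) -> None:
        if len(self.pH) != len(self.absorbance):
            raise ValueError("pH and absorbance must have equal length")


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray | None):
    """Weighted straight-line fit; returns (slope, intercept, slope_se, intercept_se)."""
    X = np.column_stack([np.ones_like(x), x])
    if w is None:
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = max(len(x) - 2, 1)
        s2 = float(res[0]) / dof if res.size else float(np.sum((y - X @ beta) ** 2)) / dof
        cov = s2 * np.linalg.inv(X.T @ X)
    else:
        W = np.diag(w)
        cov = np.linalg.inv(X.T @ W @ X)
        beta = cov @ X.T @ W @ y
    return beta[1], beta[0], math.sqrt(cov[1, 1]), math.sqrt(cov[0, 0])


def fit_bell(
    rates: Sequence[RateEstimate],
    constants: Constants = DEFAULT_CONSTANTS,
    compound_name: str = "",
) -> LandscapeFit:
    """Weighted linear regression of ln(normalized rate) on force.

    Weights are the inverse variances of ln r obtained from the bootstrap
    SDs by the delta method (sd_ln = sd/r); falls back to an unweighted fit
    when any SD is zero/absent.  The pre-exponential A is treated as exact,
    so the barrier uncertainty propagates only the intercept SD.
    """
    F = np.array([r.force_pN for r in rates], dtype=float)
    rn = np.array([r.concentration_normalized_rate_M_s for r in rates], dtype=float)
    if len(np.unique(F)) < 2:
        raise ValueError("Bell fit requires >= 2 distinct forces")
    if np.any(~np.isfinite(rn)) or np.any(rn <= 0):
        raise ValueError("all rates must be positive and concentration-normalized")
    y = np.log(rn)
    sd_ln = np.array([r.rate_sd_s / r.rate_s if r.rate_sd_s > 0 else 0.0 for r in rates])
    w = 1.0 / sd_ln**2 if np.all(sd_ln > 0) else None
    slope, intercept, slope_se, intercept_se = _wls_line(F, y, w)
    dx_A = slope * constants.kT_pN_nm * 10.0
    r0 = math.exp(intercept)
    return LandscapeFit(
        dx_A=dx_A,
        r0_norm_M_s=r0,
        dG_barrier_kT=barrier_from_rate(r0, constants),
        dx_sd_A=slope_se * constants.kT_pN_nm * 10.0,
        r0_sd_M_s=r0 * intercept_se,
        dG_barrier_sd_kT=intercept_se,
        n_forces=len(np.unique(F)),
        compound_name=compound_name,
    )


def fit_pka(data: TitrationData) -> TitrationData:
    """Henderson-Hasselbalch fit of an absorbance-pH titration.

    Free parameters: A_min, A_max and the pKa (titration midpoint).  The
    absorbance must increase with pH (thiolate absorbs at 240 nm).
    """
    pH = np.asarray(data.pH, dtype=float)
    a = np.asarray(data.absorbance, dtype=float)
    if pH.size < 4:
        raise ValueError("titration fit needs >= 4 pH points")
    if np.ptp(a) <= 0:
        raise ValueError("degenerate (flat) titration data")
    if stats.linregress(pH, a).slope <= 0:
        raise ValueError("absorbance must increase with pH (wrong orientation)")
    half = a.min() + 0.5 * np.ptp(a)
    p0 = [a.min(), a.max(), float(pH[np.argmin(np.abs(a - half))])]
    popt, pcov = curve_fit(
        lambda x, lo, hi, pka: lo + (hi - lo) / (1.0 + 10.0 ** (pka - x)), pH, a, p0=p0
    )
    pka, pka_sd = float(popt[2]), float(math.sqrt(pcov[2, 2]))
    if not (pH.min() <= pka <= pH.max()):
        warnings.warn(
            f"fitted pKa {pka:.2f} lies outside the measured pH span "
            f"[{pH.min():.2f}, {pH.max():.2f}]",
            stacklevel=2,
        )
    return replace(data, pKa_fit=pka, pKa_sd=pka_sd)


def charge_rate_regression(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Ordinary least squares on paired observables; returns (slope,
    intercept, r^2).

    Used both for the rate-vs-sulfur-charge correlation and the
    reformation-vs-pKa correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("regression needs >= 3 points")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
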