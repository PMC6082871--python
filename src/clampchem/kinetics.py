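"""Reduction rate constants from ensembles of accepted trajectories.

Follows the standard force-clamp workflow: the cumulative reduction
extension of every accepted recording is aligned at the test-pulse onset,
normalized by its own total reduction extension, averaged pointwise over
recordings, and the summed trace is fitted with a single exponential
1 - exp(-r t).  Uncertainty comes from bootstrap resampling of whole
recordings (default 500 resamples); the point estimate is always the fit
to the full ensemble, not the mean over resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .detect import EventSet

__all__ = ["SummedTrace", "RateEstimate", "sum_and_normalize", "fit_exponential", "bootstrap_rate"]


@dataclass(frozen=True)
class SummedTrace:
    """Mean normalized cumulative reduction extension on a common grid."""

    time_s: np.ndarray
    fraction: np.ndarray
    n_traces: int


@dataclass(frozen=True)
class RateEstimate:
    rate_s: float
    rate_sd_s: float
    n_traces: int
    n_bootstrap: int
    force_pN: float
    concentration_normalized_rate_M_s: float = float("nan")

    def __post_init__(self) -> None:
        if self.rate_s <= 0:
            raise ValueError("rate must be > 0")
        if self.rate_sd_s < 0:
            raise ValueError("rate SD must be >= 0")


def _reduction_staircases(
    event_sets: Sequence[EventSet], grid_hz: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-trace normalized cumulative-extension staircases on a common grid."""
    if len(event_sets) == 0:
        raise ValueError("need at least one accepted trace")
    for es in event_sets:
        if not es.accepted:
            raise ValueError(f"trace {es.trajectory_id!r} was not accepted: {es.rejection_reason}")
    forces = {round(es.test_force_pN, 6) for es in event_sets}
    names = {es.compound_name for es in event_sets}
    if len(forces) > 1 or len(names) > 1:
        raise ValueError(f"mixed conditions: forces {forces}, compounds {names}")
    duration = max(es.test_duration_s for es in event_sets)
    grid = np.arange(0.0, duration + 0.5 / grid_hz, 1.0 / grid_hz)
    mat = np.empty((len(event_sets), grid.size))
    for i, es in enumerate(event_sets):
        # every step in the test pulse of an accepted trace is reduction
        # extension (the kinetics filter bars unfolding there); merged
        # near-simultaneous cleavages thus contribute their full size
        red = [e for e in es.in_segment("test")]
        total = sum(e.size_nm for e in red)
        if total <= 0:
            raise ValueError(f"trace {es.trajectory_id!r} has zero reduction extension")
        times = np.array([e.time_s - es.test_onset_s for e in red])
        sizes = np.array([e.size_nm for e in red]) / total
        order = np.argsort(times)
        cum = np.cumsum(sizes[order])
        idx = np.searchsorted(times[order], grid, side="right")
        mat[i] = np.concatenate([[0.0], cum])[idx]
    return grid, mat, duration


def sum_and_normalize(event_sets: Sequence[EventSet], grid_hz: float = 100.0) -> SummedTrace:
    """Summed, normalized reduction trace of one (compound, force) condition."""
    grid, mat, _ = _reduction_staircases(event_sets, grid_hz)
    return SummedTrace(time_s=grid, fraction=mat.mean(axis=0), n_traces=mat.shape[0])


def _fit_rate(t: np.ndarray, y: np.ndarray) -> float:
    # initial guess from the time the curve crosses 1 - 1/e
    above = np.nonzero(y >= 0.632)[0]
    t63 = t[above[0]] if above.size and above[0] > 0 else (t[-1] / 2 or 1.0)
    p0 = 1.0 / max(t63, t[1] if t.size > 1 else 1.0)
    popt, _ = curve_fit(
        lambda tt, r: -np.expm1(-r * tt), t, y, p0=[p0], bounds=(1e-9, np.inf)
    )
    return float(popt[0])


def fit_exponential(
    trace: SummedTrace,
    thiolate_concentration_M: float | None = None,
    force_pN: float = float("nan"),
) -> RateEstimate:
    """Least-squares single-exponential fit 1 - exp(-r t) of a summed trace."""
    t, y = np.asarray(trace.time_s), np.asarray(trace.fraction)
    if np.any(np.diff(y) < -1e-9):
        raise ValueError("summed trace must be non-decreasing")
    if np.ptp(y) < 0.05:
        raise ValueError("degenerate (flat) summed trace")
    rate = _fit_rate(t, y)
    if t[-1] < 3.0 / rate:
        warnings.warn(
            f"trace spans {t[-1]:.3g} s < 3/r = {3.0 / rate:.3g} s; "
            "the fitted rate may be censoring-biased",
            stacklevel=2,
        )
    norm = rate / thiolate_concentration_M if thiolate_concentration_M else float("nan")
    return RateEstimate(rate, 0.0, trace.n_traces, 0, force_pN, norm)


def bootstrap_rate(
    event_sets: Sequence[EventSet],
    n_bootstrap: int = 500,
    seed: int = 0,
    grid_hz: float = 100.0,
    thiolate_concentration_M: float | None = None,
) -> RateEstimate:
    """Rate with bootstrap SD: recordings resampled with replacement,
    each resample re-summed and refitted.  Seeded and reproducible."""
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    if len(event_sets) < 2:
        raise ValueError("bootstrap requires at least 2 traces")
    grid, mat, _ = _reduction_staircases(event_sets, grid_hz)
    rate = _fit_rate(grid, mat.mean(axis=0))
    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    resampled = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            resampled[b] = _fit_rate(grid, mat[idx].mean(axis=0))
        except RuntimeError:  # pragma: no cover - pathological resample
            resampled[b] = np.nan
    sd = float(np.nanstd(resampled, ddof=1))
    force = event_sets[0].test_force_pN
    norm = rate / thiolate_concentration_M if thiolate_concentration_M else float("nan")
    return RateEstimate(rate, sd, n, n_bootstrap, force, norm)
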