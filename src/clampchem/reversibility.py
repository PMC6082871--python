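"""Disulfide reformation after force quench: outcome models and scoring.

When the stretching force is removed, the collapsed protein's reduced
thiolate can re-attack the mixed disulfide.  With an 8 s quench the
partition between outcomes is under thermodynamic control, so the simplest
model is a two-state Boltzmann between the reformed native bond and the
retained mixed disulfide (the reverse of the reduction reaction).  A
three-state variant adds the fully reduced protein (mixed disulfide
displaced by a second solution thiolate, forming the thiol homodimer), and
an empirical linear model reproduces the graded reformation-vs-pKa trend
observed across nucleophiles, which the pure thermodynamic limits
overstate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CompoundParams, Constants, DEFAULT_CONSTANTS, equilibrium_reformation_fraction
from .detect import EventSet
from .landscape import charge_rate_regression

__all__ = [
    "QuenchOutcome",
    "ReformationResult",
    "quench_partition",
    "score_reformation",
    "reformation_pka_correlation",
    "EMPIRICAL_SLOPE_PER_PKA",
    "EMPIRICAL_INTERCEPT",
]

# Empirical linear reformation-vs-pKa calibration (clamped to [0, 1]):
# anchored so a ~9.1-pKa thiolate (mesna-like, strongly favored reduction)
# reforms ~3-5% while a ~6.6-pKa one (Cys-ME-like) reforms ~70%.
EMPIRICAL_SLOPE_PER_PKA = -0.26
EMPIRICAL_INTERCEPT = 2.416

QUENCH_MODELS = ("equilibrium2", "boltzmann3", "empirical_linear")


@dataclass(frozen=True)
class QuenchOutcome:
    """Per-bond outcome probabilities during the zero-force quench."""

    p_reform: float
    p_mixed: float
    p_full_reduced: float
    model: str

    def __post_init__(self) -> None:
        probs = (self.p_reform, self.p_mixed, self.p_full_reduced)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")


@dataclass(frozen=True)
class ReformationResult:
    """Pooled reformation fraction of one compound's five-pulse cohort."""

    fraction_reformed: float
    fraction_sd: float
    n_traces: int
    compound_name: str
    quench_time_s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_reformed <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")
        if self.quench_time_s <= 0:
            raise ValueError("quench_time_s must be > 0")


def quench_partition(
    compound: CompoundParams,
    dG0_homodimer_kcal_mol: float | None = None,
    quench_time_s: float = 8.0,
    model: str = "equilibrium2",
    constants: Constants = DEFAULT_CONSTANTS,
    k_reverse_s: float | None = None,
) -> QuenchOutcome:
    """Resolve a ruptured disulfide into {reformed, mixed, fully reduced}.

    Models
    ------
    equilibrium2
        Two-state Boltzmann between mixed disulfide and reformed native
        bond; p_reform = 1 / (1 + exp(-dG0_red / kT)).
    boltzmann3
        Three-state Boltzmann with energies 0 (native + thiolate),
        dG0/kT (mixed disulfide) and (dG0 + dG0_homodimer)/kT (fully
        reduced + thiol homodimer).  ``dG0_homodimer`` defaults to the
        compound's dG0 (symmetric-exchange placeholder; not an experimental
        value).
    empirical_linear
        p_reform = clamp(a * pKa + b, 0, 1) with the packaged calibration.

    ``k_reverse_s``, if given, replaces the instantaneous equilibrium with a
    first-order relaxation p(t_q) = p_eq * (1 - exp(-k t_q)) for
    sensitivity analysis; the defect mass stays in the mixed state.
    """
    if model not in QUENCH_MODELS:
        raise ValueError(f"unknown model {model!r}; supported: {QUENCH_MODELS}")
    if quench_time_s <= 0:
        raise ValueError("quench_time_s must be > 0")
    dg0 = compound.dG0_kcal_mol
    if model == "equilibrium2":
        p_reform = equilibrium_reformation_fraction(dg0, constants)
        probs = [p_reform, 1.0 - p_reform, 0.0]
    elif model == "boltzmann3":
        dghd = dg0 if dG0_homodimer_kcal_mol is None else dG0_homodimer_kcal_mol
        energies = np.array([0.0, dg0, dg0 + dghd]) / constants.kT_kcal_mol
        w = np.exp(-(energies - energies.min()))
        probs = list(w / w.sum())
    else:
        p_reform = min(max(EMPIRICAL_SLOPE_PER_PKA * compound.pKa + EMPIRICAL_INTERCEPT, 0.0), 1.0)
        probs = [p_reform, 1.0 - p_reform, 0.0]
    if k_reverse_s is not None:
        scale = -math.expm1(-k_reverse_s * quench_time_s)
        moved = probs[0] * (1.0 - scale)
        probs = [probs[0] - moved, probs[1] + moved, probs[2]]
    return QuenchOutcome(*probs, model=model)


def score_reformation(
    event_sets: Sequence[EventSet],
    n_bootstrap: int = 500,
    seed: int = 0,
    quench_time_s: float = 8.0,
) -> ReformationResult:
    """Pooled reformation fraction with bootstrap SD over recordings.

    fraction = (total probe-pulse reduction events) / (total first-pulse
    rupture events), pooled event-wise across accepted traces; each
    recording is one independent bootstrap unit.  Reformation is only
    defined for bonds ruptured in the first pulse, so a trace's probe count
    is capped at its rupture count (domains whose intact disulfide survived
    the first high-force pulse can cleave in the probe pulse and would
    otherwise contaminate the numerator).
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    accepted = [es for es in event_sets if es.accepted]
    if not accepted:
        raise ValueError("no accepted traces to score")
    ruptures = np.array(
        [len([e for e in es.in_segment("test") if e.event_class == "reduction"]) for es in accepted],
        dtype=float,
    )
    probes = np.array(
        [len([e for e in es.in_segment("probe") if e.event_class == "reform_probe"]) for es in accepted],
        dtype=float,
    )
    probes = np.minimum(probes, ruptures)
    fraction = float(probes.sum() / ruptures.sum())
    rng = np.random.default_rng(seed)
    n = len(accepted)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boot[b] = probes[idx].sum() / max(ruptures[idx].sum(), 1.0)
    return ReformationResult(
        fraction_reformed=fraction,
        fraction_sd=float(np.std(boot, ddof=1)),
        n_traces=n,
        compound_name=accepted[0].compound_name,
        quench_time_s=quench_time_s,
    )


def reformation_pka_correlation(
    results: Sequence[ReformationResult],
    pKas: Sequence[float] | None = None,
    abscissa: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Linear regression of reformation percentage on pKa (or on a supplied
    abscissa such as dG0); returns (slope, intercept, r^2)."""
    if abscissa is None:
        if pKas is None:
            raise ValueError("provide pKas or an explicit abscissa")
        abscissa = pKas
    if len(abscissa) != len(results):
        raise ValueError("abscissa and results must have equal length")
    percent = [100.0 * r.fraction_reformed for r in results]
    return charge_rate_regression(abscissa, percent)
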