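"""Seeded stochastic generator of force-clamp trajectories.

Emulates the statistical structure of constant-force AFM recordings of an
8-repeat disulfide-containing polyprotein: per-domain unfolding as
exponential waiting times with a Bell-type force dependence, a subsequent
exponential SN2 cleavage clock per exposed disulfide, fixed ~15 nm / ~10 nm
extension fingerprints, first-order force-feedback settling, and additive
Gaussian extension noise.  Reformation (five-pulse) protocols additionally
resolve every ruptured bond during the zero-force quench into one of
{reformed, mixed-disulfide retained, fully reduced} according to a
quench-partition model.

All randomness flows from integer seeds; identical seeds give bit-identical
trajectories.  Cohorts derive one child seed per (compound, force,
replicate) from the root seed through ``numpy.random.SeedSequence`` so the
collection is reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CompoundParams,
    Constants,
    DEFAULT_CONSTANTS,
    ForceProtocol,
    bell_rate,
    titration_absorbance,
)
from .detect import StepEvent
from .landscape import TitrationData
from .reversibility import QuenchOutcome, quench_partition

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "simulate_kinetics_trace",
    "simulate_reformation_trace",
    "generate_cohort",
    "simulate_titration",
    "exponential_waiting_times",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults are the packaged study conditions.

    Unfolding kinetics (rate 10 s^-1 per domain at 150 pN, dx 2.5 A) are
    chosen so that typically all, and nearly always >= 5, of the 8 domains
    unfold within the 0.5 s / 150 pN pulse.
    """

    n_domains: int = 8
    step_unfold_nm: float = 15.0
    step_reduce_nm: float = 10.0
    step_size_sd_nm: float = 1.0
    noise_sd_nm: float = 1.0
    sample_rate_Hz: float = 1000.0
    feedback_tau_s: float = 0.002
    unfold_rate_150pN_s: float = 10.0
    dx_unfold_A: float = 2.5
    seed: int = 0
    n_traces: int = 100

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        for name in ("step_unfold_nm", "step_reduce_nm", "sample_rate_Hz", "unfold_rate_150pN_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd_nm < 0 or self.feedback_tau_s < 0 or self.step_size_sd_nm < 0:
            raise ValueError("noise, settling time and step SD must be >= 0")


@dataclass
class Trajectory:
    """One sampled (time, force, extension) record with hidden ground truth."""

    time_s: np.ndarray
    force_pN: np.ndarray
    extension_nm: np.ndarray
    true_events: list[StepEvent]
    protocol: ForceProtocol
    compound_name: str
    seed: int
    sample_rate_Hz: float
    feedback_tau_s: float
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.time_s) == len(self.force_pN) == len(self.extension_nm)):
            raise ValueError("time, force and extension must have equal length")


def exponential_waiting_times(rate_s: float, n: int, seed: int) -> np.ndarray:
    """n waiting times from the simulator's clock machinery at constant rate.

    Draws through the same hazard-integration path used inside trajectory
    generation, so survival statistics of simulated events can be checked
    against the closed form exp(-rate * t).
    """
    rng = np.random.default_rng(seed)
    e = rng.exponential(1.0, size=n)
    return e / rate_s


def _first_passage(
    bounds: np.ndarray, rates: Sequence[float], t_start: float, e: float
) -> float:
    """Time at which the integrated piecewise-constant hazard reaches e.

    ``bounds`` are segment edges (len = n_seg + 1), ``rates`` the hazard in
    each segment.  Returns inf when the total hazard after t_start is
    insufficient.
    """
    acc = 0.0
    for i, rate in enumerate(rates):
        a = max(bounds[i], t_start)
        b = bounds[i + 1]
        if b <= a or rate <= 0.0:
            continue
        seg_hazard = rate * (b - a)
        if acc + seg_hazard >= e:
            return a + (e - acc) / rate
        acc += seg_hazard
    return np.inf


def _unfold_rates(protocol: ForceProtocol, config: SimulationConfig, constants: Constants) -> list[float]:
    dx_nm = config.dx_unfold_A / 10.0
    rates = []
    for seg in protocol.segments:
        if seg.label == "quench":
            rates.append(0.0)
        else:
            rates.append(
                config.unfold_rate_150pN_s
                * np.exp((seg.force_pN - 150.0) * dx_nm / constants.kT_pN_nm)
            )
    return rates


def _reduction_rates(
    protocol: ForceProtocol, compound: CompoundParams, constants: Constants
) -> list[float]:
    return [
        0.0 if seg.label == "quench" else float(bell_rate(seg.force_pN, compound, constants))
        for seg in protocol.segments
    ]


def _render_extension(
    t: np.ndarray,
    events: list[StepEvent],
    config: SimulationConfig,
    rng: np.random.Generator,
    reset_windows: list[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Staircase of step responses with first-order settling plus noise.

    ``reset_windows`` are (start, end) intervals during which the tether is
    collapsed (extension ~ 0); the staircase restarts from zero afterwards.
    """
    ext = np.zeros_like(t)
    tau = config.feedback_tau_s
    resets = reset_windows or []
    for ev in events:
        onset = ev.time_s
        if tau > 0:
            resp = np.where(t >= onset, -np.expm1(-np.maximum(t - onset, 0.0) / tau), 0.0)
        else:
            resp = (t >= onset).astype(float)
        ext += ev.size_nm * resp
    for a, b in resets:
        in_quench = (t >= a) & (t < b)
        ext[in_quench] = 0.0
        # events before the quench do not carry over into later pulses
        pre = sum(ev.size_nm for ev in events if ev.time_s < a)
        ext[t >= b] -= pre
    if config.noise_sd_nm > 0:
        ext = ext + rng.normal(0.0, config.noise_sd_nm, size=t.size)
    return ext


def _time_axis(protocol: ForceProtocol, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / config.sample_rate_Hz
    n = int(round(protocol.total_duration_s / dt))
    t = np.arange(n) * dt
    bounds = protocol.boundaries_s()
    force = np.empty(n)
    for i, seg in enumerate(protocol.segments):
        force[(t >= bounds[i]) & (t < bounds[i + 1])] = seg.force_pN
    return t, force


def _segment_of(protocol: ForceProtocol, time_s: float) -> int:
    bounds = protocol.boundaries_s()
    return min(int(np.searchsorted(bounds, time_s, side="right")) - 1, len(protocol.segments) - 1)


def _step_size(mean_nm: float, config: SimulationConfig, rng: np.random.Generator) -> float:
    if config.step_size_sd_nm == 0:
        return mean_nm
    return float(rng.normal(mean_nm, config.step_size_sd_nm))


def simulate_kinetics_trace(
    compound: CompoundParams,
    protocol: ForceProtocol,
    config: SimulationConfig,
    constants: Constants = DEFAULT_CONSTANTS,
    trajectory_id: str = "",
) -> Trajectory:
    """Two-pulse (unfold, then high-force test) kinetics trajectory.

    Each domain unfolds after an exponential waiting time with the Bell
    force dependence of the unfolding rate; once unfolded, its disulfide is
    cleaved by an independent exponential clock at ``bell_rate(F)``.
    """
    labels = protocol.labels()
    if "test" not in labels:
        raise ValueError("kinetics protocol requires a test segment")
    if labels != ["unfold", "test"]:
        raise ValueError("kinetics protocol must be exactly unfold-then-test")
    rng = np.random.default_rng(config.seed)
    bounds = protocol.boundaries_s()
    ku = _unfold_rates(protocol, config, constants)
    kr = _reduction_rates(protocol, compound, constants)

    events: list[StepEvent] = []
    for _ in range(config.n_domains):
        t_u = _first_passage(bounds, ku, 0.0, rng.exponential(1.0))
        if not np.isfinite(t_u):
            continue
        si = _segment_of(protocol, t_u)
        events.append(
            StepEvent(t_u, _step_size(config.step_unfold_nm, config, rng), "unfold", labels[si], si)
        )
        t_r = _first_passage(bounds, kr, t_u, rng.exponential(1.0))
        if np.isfinite(t_r):
            si = _segment_of(protocol, t_r)
            cls = "reform_probe" if labels[si] == "probe" else "reduction"
            events.append(
                StepEvent(t_r, _step_size(config.step_reduce_nm, config, rng), cls, labels[si], si)
            )
    events.sort(key=lambda e: e.time_s)

    t, force = _time_axis(protocol, config)
    ext = _render_extension(t, events, config, rng)
    return Trajectory(
        t, force, ext, events, protocol, compound.name, config.seed,
        config.sample_rate_Hz, config.feedback_tau_s, trajectory_id,
    )


def simulate_reformation_trace(
    compound: CompoundParams,
    protocol: ForceProtocol,
    config: SimulationConfig,
    reformation_model: str | float | QuenchOutcome = "equilibrium2",
    constants: Constants = DEFAULT_CONSTANTS,
    trajectory_id: str = "",
) -> Trajectory:
    """Five-pulse reformation trajectory.

    Pulses 1-2 run the kinetics assay; during the zero-force quench every
    ruptured disulfide resolves to {reformed, mixed retained, fully reduced}
    according to ``reformation_model`` (a model name, a fixed reformation
    probability, or an explicit :class:`QuenchOutcome`).  Reformed bonds
    replay unfolding and cleavage in the probe pulses; non-reformed domains
    refold without the disulfide staple and release their full length in a
    single ~25 nm step when re-stretched.
    """
    labels = protocol.labels()
    if "quench" not in labels or "probe" not in labels:
        raise ValueError("reformation protocol requires quench and probe segments")
    qi = labels.index("quench")
    if protocol.segments[qi].force_pN != 0.0:
        raise ValueError("quench segment must be at zero force")
    if labels.index("probe") < qi:
        raise ValueError("probe segment must follow the quench")

    if isinstance(reformation_model, QuenchOutcome):
        outcome = reformation_model
    elif isinstance(reformation_model, (int, float)):
        p = float(reformation_model)
        outcome = QuenchOutcome(p, 1.0 - p, 0.0, model="fixed")
    else:
        outcome = quench_partition(
            compound,
            quench_time_s=protocol.segments[qi].duration_s,
            model=reformation_model,
            constants=constants,
        )

    rng = np.random.default_rng(config.seed)
    bounds = protocol.boundaries_s()
    quench_start, quench_end = bounds[qi], bounds[qi + 1]
    ku = _unfold_rates(protocol, config, constants)
    kr = _reduction_rates(protocol, compound, constants)

    def clocks(t_from: float) -> tuple[float, float]:
        t_u = _first_passage(bounds, ku, t_from, rng.exponential(1.0))
        t_r = (
            _first_passage(bounds, kr, t_u, rng.exponential(1.0))
            if np.isfinite(t_u)
            else np.inf
        )
        return t_u, t_r

    def add_event(t_e: float, mean_nm: float, cls: str | None) -> None:
        si = _segment_of(protocol, t_e)
        label = labels[si]
        if cls is None:
            cls = "reform_probe" if label == "probe" else "reduction"
        events.append(StepEvent(t_e, _step_size(mean_nm, config, rng), cls, label, si))

    events: list[StepEvent] = []
    probabilities = [outcome.p_reform, outcome.p_mixed, outcome.p_full_reduced]
    for _ in range(config.n_domains):
        t_u, t_r = clocks(0.0)
        ruptured = np.isfinite(t_r) and t_r < quench_start
        if np.isfinite(t_u) and t_u < quench_start:
            add_event(t_u, config.step_unfold_nm, "unfold")
        if ruptured:
            add_event(t_r, config.step_reduce_nm, None)
            fate = rng.choice(3, p=probabilities)
        else:
            fate = 0  # intact (or never-exposed) disulfide survives the quench
        if fate == 0:
            # native bond present after the quench: fresh unfold + cleavage clocks
            t_u2, t_r2 = clocks(quench_end)
            if np.isfinite(t_u2):
                add_event(t_u2, config.step_unfold_nm, "unfold")
                if np.isfinite(t_r2):
                    add_event(t_r2, config.step_reduce_nm, None)
        else:
            # no disulfide staple: the refolded domain releases its full
            # length in one step when re-stretched
            t_u2 = _first_passage(bounds, ku, quench_end, rng.exponential(1.0))
            if np.isfinite(t_u2):
                size = _step_size(config.step_unfold_nm, config, rng) + _step_size(
                    config.step_reduce_nm, config, rng
                )
                si = _segment_of(protocol, t_u2)
                events.append(StepEvent(t_u2, size, "unclassified", labels[si], si))
    events.sort(key=lambda e: e.time_s)

    t, force = _time_axis(protocol, config)
    ext = _render_extension(t, events, config, rng, reset_windows=[(quench_start, quench_end)])
    return Trajectory(
        t, force, ext, events, protocol, compound.name, config.seed,
        config.sample_rate_Hz, config.feedback_tau_s, trajectory_id,
    )


def child_seed(root_seed: int, *key: int) -> int:
    """Deterministic, order-independent per-trajectory seed (< 2^31)."""
    ss = np.random.SeedSequence([int(root_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def default_test_duration_s(
    compound: CompoundParams, force_pN: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Test-pulse length spanning ~8 mean lifetimes (clipped to 5-60 s).

    Mirrors the experimental practice of holding the high-force pulse for a
    'large, variable period of time' so the full cleavage kinetics of each
    nucleophile are captured.
    """
    rate = float(bell_rate(force_pN, compound, constants))
    return float(np.clip(8.0 / rate, 5.0, 60.0))


def generate_cohort(
    compounds: Sequence[CompoundParams],
    forces: Sequence[float],
    config: SimulationConfig,
    protocol_factory=None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Kinetics cohort: ``config.n_traces`` trajectories per (compound, force).

    Child seeds are derived per (compound index, force index, replicate), so
    the same call is bit-reproducible and independent of iteration order.
    Returns the trajectories and a manifest table.
    """
    if len(compounds) == 0 or len(forces) == 0:
        raise ValueError("compounds and forces must be non-empty")
    names = [c.name for c in compounds]
    if len(set(names)) != len(names) or len(set(forces)) != len(forces):
        raise ValueError("duplicate (compound, force) keys in cohort request")
    trajectories: list[Trajectory] = []
    rows = []
    for ci, compound in enumerate(compounds):
        for fi, force in enumerate(forces):
            if protocol_factory is None:
                from .core import two_pulse_protocol

                protocol = two_pulse_protocol(force, default_test_duration_s(compound, force, constants))
            else:
                protocol = protocol_factory(compound, force)
            for ri in range(config.n_traces):
                seed = child_seed(config.seed, ci, fi, ri)
                tid = f"{compound.name}_F{force:g}_r{ri}"
                traj = simulate_kinetics_trace(
                    compound,
                    protocol,
                    replace(config, seed=seed),
                    constants,
                    trajectory_id=tid,
                )
                trajectories.append(traj)
                rows.append(
                    dict(trajectory_id=tid, compound=compound.name, force_pN=force,
                         replicate=ri, seed=seed, n_true_events=len(traj.true_events))
                )
    return trajectories, pd.DataFrame(rows)


def simulate_titration(
    pKa_true: float,
    pH_grid: Sequence[float],
    noise_sd: float,
    seed: int,
    A_min: float = 0.1,
    A_max: float = 0.9,
) -> TitrationData:
    """Noisy absorbance-vs-pH titration curve around a known pKa."""
    pH = np.asarray(pH_grid, dtype=float)
    if pH.size < 4 or not (pH.min() < pKa_true < pH.max()):
        warnings.warn(
            "pH grid does not bracket the titration midpoint with enough points; "
            "the fitted pKa will be poorly constrained",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    a = np.asarray(titration_absorbance(pH, A_min, A_max, pKa_true), dtype=float)
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=pH.size)
    return TitrationData(pH=pH, absorbance=a)
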