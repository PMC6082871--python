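"""Domain types and closed-form physics of thiol-disulfide mechanochemistry.

The model system is a protein disulfide bond stretched at constant force and
attacked by a small thiolate nucleophile (bimolecular SN2 exchange).  The
closed forms collected here are shared by every downstream stage:

* protonation equilibria (Henderson-Hasselbalch) setting the active
  thiolate concentration,
* the Bell/Arrhenius force-accelerated rate law
  ``r(F) = A [S-] exp(-dG_barrier) exp(F dx / kBT)``,
* the two-state Boltzmann partition governing disulfide reformation after
  the force is quenched, and
* a three-level 1D free-energy landscape (reactant well, transition state,
  mixed-disulfide product well).

Units: forces in pN, distances in nm internally (angstrom at interfaces),
energies in kT at 298 K with explicit conversion from kcal/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "Constants",
    "CompoundParams",
    "ProtocolSegment",
    "ForceProtocol",
    "ThreeStateLandscape",
    "deprotonated_fraction",
    "bell_rate",
    "barrier_from_rate",
    "equilibrium_reformation_fraction",
    "titration_absorbance",
    "build_landscape",
    "load_compound_table",
    "two_pulse_protocol",
    "five_pulse_protocol",
    "DEFAULT_CONSTANTS",
]

SEGMENT_LABELS = ("unfold", "test", "quench", "probe")


@dataclass(frozen=True)
class Constants:
    """Physical constants at 298 K.

    kT_pN_nm and kT_kcal_mol must agree (through J <-> kcal/mol) within 1%;
    A_prefactor_M_s is the bimolecular pre-exponential used to convert
    zero-force rates into activation barriers.
    """

    kT_pN_nm: float = 4.114
    kT_kcal_mol: float = 0.5925
    A_prefactor_M_s: float = 1.0e7

    def __post_init__(self) -> None:
        if not (self.kT_pN_nm > 0 and self.kT_kcal_mol > 0 and self.A_prefactor_M_s > 0):
            raise ValueError("all constants must be strictly positive")
        # pN*nm = 1e-21 J; kcal/mol / N_A = J
        j_from_pn_nm = self.kT_pN_nm * 1e-21
        j_from_kcal = self.kT_kcal_mol * 4184.0 / 6.02214076e23
        if abs(j_from_pn_nm - j_from_kcal) / j_from_kcal > 0.01:
            raise ValueError("kT values inconsistent beyond 1%")


DEFAULT_CONSTANTS = Constants()


@dataclass(frozen=True)
class CompoundParams:
    """Physical constants of one small-thiol nucleophile.

    dG0_kcal_mol is the standard free energy of disulfide *reduction* by
    this thiol (negative = spontaneous); dG_barrier_kT the zero-force
    activation free energy; dx_A the distance to the transition state.
    sulfur_charge_e (optional) is the partial charge on the nucleophilic
    sulfur used only for rate-charge correlations.
    """

    name: str
    pKa: float
    dG0_kcal_mol: float
    dx_A: float
    dG_barrier_kT: float
    total_concentration_M: float
    pH: float
    sulfur_charge_e: float | None = None

    def __post_init__(self) -> None:
        if not (5.0 <= self.pKa <= 12.0):
            raise ValueError(f"pKa {self.pKa} outside [5, 12]")
        if not (0.0 < self.dx_A < 2.0):
            raise ValueError(f"dx_A {self.dx_A} outside (0, 2) angstrom")
        if self.dG_barrier_kT <= 0:
            raise ValueError("dG_barrier_kT must be > 0")
        if self.total_concentration_M <= 0:
            raise ValueError("total_concentration_M must be > 0")

    @property
    def dx_nm(self) -> float:
        return self.dx_A / 10.0

    def thiolate_concentration_M(self) -> float:
        """Active (deprotonated) concentration [S-] at the stored pH."""
        return self.total_concentration_M * deprotonated_fraction(self.pKa, self.pH)


@dataclass(frozen=True)
class ProtocolSegment:
    force_pN: float
    duration_s: float
    label: str

    def __post_init__(self) -> None:
        if self.force_pN < 0:
            raise ValueError("force_pN must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"label must be one of {SEGMENT_LABELS}")


@dataclass(frozen=True)
class ForceProtocol:
    """Ordered constant-force segments defining one experiment."""

    segments: tuple[ProtocolSegment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError("protocol must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))

    def boundaries_s(self) -> np.ndarray:
        """Segment start/end times, length n_segments + 1."""
        return np.concatenate([[0.0], np.cumsum([s.duration_s for s in self.segments])])

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    def segment_index(self, label: str, occurrence: int = 0) -> int:
        idx = [i for i, s in enumerate(self.segments) if s.label == label]
        if len(idx) <= occurrence:
            raise ValueError(f"protocol has no segment '{label}' (occurrence {occurrence})")
        return idx[occurrence]


def two_pulse_protocol(
    test_force_pN: float,
    test_duration_s: float,
    unfold_force_pN: float = 150.0,
    unfold_duration_s: float = 0.5,
) -> ForceProtocol:
    """Unfold-then-test kinetics protocol (150 pN / 0.5 s unfold by default)."""
    return ForceProtocol(
        (
            ProtocolSegment(unfold_force_pN, unfold_duration_s, "unfold"),
            ProtocolSegment(test_force_pN, test_duration_s, "test"),
        )
    )


def five_pulse_protocol(
    test_force_pN: float,
    test_duration_s: float = 5.0,
    quench_duration_s: float = 8.0,
    probe_duration_s: float = 5.0,
    unfold_force_pN: float = 150.0,
    unfold_duration_s: float = 0.5,
) -> ForceProtocol:
    """Reformation protocol: unfold, rupture, zero-force quench, re-unfold, probe."""
    return ForceProtocol(
        (
            ProtocolSegment(unfold_force_pN, unfold_duration_s, "unfold"),
            ProtocolSegment(test_force_pN, test_duration_s, "test"),
            ProtocolSegment(0.0, quench_duration_s, "quench"),
            ProtocolSegment(unfold_force_pN, unfold_duration_s, "unfold"),
            ProtocolSegment(test_force_pN, probe_duration_s, "probe"),
        )
    )


@dataclass(frozen=True)
class ThreeStateLandscape:
    """1D free-energy landscape: reactant well, transition state, product well.

    Reference zero is the intact disulfide + free thiolate; the product well
    is the mixed disulfide + reduced protein thiolate.
    """

    g_reactant_kT: float
    g_ts_kT: float
    g_product_kT: float

    def __post_init__(self) -> None:
        if self.g_ts_kT < max(self.g_reactant_kT, self.g_product_kT) - 1e-9:
            raise ValueError("transition state must lie above both wells")


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


def deprotonated_fraction(pKa: float, pH: float) -> float:
    """Fraction of thiol present as thiolate: 1 / (1 + 10^(pKa - pH))."""
    _check_finite(pKa=pKa, pH=pH)
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def bell_rate(
    F_pN: float | np.ndarray,
    compound: CompoundParams,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float | np.ndarray:
    """Force-accelerated SN2 cleavage rate, s^-1.

    r(F) = A [S-] exp(-dG_barrier) exp(F dx / kBT); [S-] from the compound's
    protonation equilibrium.  Strictly increasing in F; r(0) is the
    zero-force rate r0.
    """
    F = np.asarray(F_pN, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    s_minus = compound.thiolate_concentration_M()
    r0 = constants.A_prefactor_M_s * s_minus * math.exp(-compound.dG_barrier_kT)
    out = r0 * np.exp(F * compound.dx_nm / constants.kT_pN_nm)
    return float(out) if np.isscalar(F_pN) else out


def barrier_from_rate(
    r0_normalized_M_s: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Invert the zero-force rate into a barrier: ln(A / r0_norm), in kT."""
    if not (0.0 < r0_normalized_M_s <= constants.A_prefactor_M_s):
        raise ValueError(
            "concentration-normalized r0 must be in (0, A]; "
            f"got {r0_normalized_M_s!r} with A = {constants.A_prefactor_M_s!r}"
        )
    return math.log(constants.A_prefactor_M_s / r0_normalized_M_s)


def equilibrium_reformation_fraction(
    dG0_reduction_kcal_mol: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Probability the native disulfide reforms at zero force, two-state model.

    Reformation is the reverse of reduction, so K_rev = exp(+dG0_red / kT)
    and p_reform = K_rev / (1 + K_rev).  At dG0 = 0 the partition is 50:50
    (the cysteine/cystine equilibrium); monotone increasing in dG0_red.
    """
    _check_finite(dG0_reduction_kcal_mol=dG0_reduction_kcal_mol)
    # computed in log space to stay exact in the far tails
    x = dG0_reduction_kcal_mol / constants.kT_kcal_mol
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x) / (1.0 + math.exp(x))


def titration_absorbance(
    pH: float | np.ndarray, A_min: float, A_max: float, pKa: float
) -> float | np.ndarray:
    """Absorbance of a thiol titration at 240 nm: logistic in pH.

    A(pH) = A_min + (A_max - A_min) * deprotonated_fraction(pKa, pH).
    """
    if A_max < A_min:
        raise ValueError("A_max must be >= A_min")
    pH_arr = np.asarray(pH, dtype=float)
    frac = 1.0 / (1.0 + 10.0 ** (pKa - pH_arr))
    out = A_min + (A_max - A_min) * frac
    return float(out) if np.isscalar(pH) else out


def build_landscape(
    compound: CompoundParams,
    F_pN: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> ThreeStateLandscape:
    """Three-level landscape under force F.

    Force tilts the barrier down by F*dx/kBT; the barrier is clamped at the
    higher of the two wells so the landscape stays physical even for forces
    beyond the regime the rate law was calibrated in.
    """
    if F_pN < 0:
        raise ValueError("force must be >= 0")
    g_product = compound.dG0_kcal_mol / constants.kT_kcal_mol
    g_ts = compound.dG_barrier_kT - F_pN * compound.dx_nm / constants.kT_pN_nm
    g_ts = max(g_ts, 0.0, g_product)
    return ThreeStateLandscape(0.0, g_ts, g_product)


def load_compound_table() -> dict[str, CompoundParams]:
    """Packaged per-nucleophile parameter table, keyed by compound name.

    pKa values span the experimentally typical ~7-10 range; barriers for the
    compounds whose zero-force kinetics are not independently tabulated are
    representative interpolations and are meant to be edited.  All
    downstream results are parameterized on this table, never hard-coded.
    """
    text = resources.files("clampchem.data").joinpath("compounds.json").read_text()
    table = {}
    for rec in json.loads(text):
        table[rec["name"]] = CompoundParams(**rec)
    return table
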