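"""Step detection and trace-acceptance filters for force-clamp staircases.

Extension records are piecewise constant within each constant-force segment:
every domain unfolding adds a ~15 nm step and every disulfide cleavage a
~10 nm step.  Detection is greedy binary segmentation on the segment mean
with a BIC-style penalty, followed by size-window classification
(unfold 15 +/- 4 nm anywhere; reduction 10 +/- 3 nm in test/probe pulses).

The acceptance filters mirror standard force-clamp practice for an
8-repeat polyprotein: 5-8 unfolding and 5-8 reduction events, no unfolding
step in the high-force pulse, and (for reformation protocols) equal total
extension in the initial and probe pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import ForceProtocol

__all__ = [
    "StepEvent",
    "EventSet",
    "detect_steps",
    "filter_kinetics_trace",
    "filter_reformation_trace",
    "UNFOLD_WINDOW_NM",
    "REDUCTION_WINDOW_NM",
]

UNFOLD_WINDOW_NM = (11.0, 19.0)
REDUCTION_WINDOW_NM = (7.0, 13.0)


@dataclass(frozen=True)
class StepEvent:
    """One detected (or ground-truth) stepwise extension increase."""

    time_s: float
    size_nm: float
    event_class: str  # unfold | reduction | reform_probe | unclassified
    segment_label: str
    segment_index: int


@dataclass
class EventSet:
    """Ordered events of one trajectory plus its acceptance verdict.

    ``segment_levels`` maps segment index -> final plateau extension (nm),
    used by the reformation extension-match filter.  Condition metadata
    (force, compound, test-pulse geometry) is carried along so kinetics
    aggregation can validate that traces are poolable.
    """

    events: list[StepEvent]
    trajectory_id: str
    accepted: bool
    rejection_reason: str = ""
    segment_levels: dict[int, float] = field(default_factory=dict)
    compound_name: str = ""
    test_force_pN: float = float("nan")
    test_onset_s: float = float("nan")
    test_duration_s: float = float("nan")
    protocol_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if times != sorted(times):
            raise ValueError("events must be time-ordered")
        if self.accepted and self.rejection_reason:
            raise ValueError("accepted EventSet cannot carry a rejection reason")

    def count(self, event_class: str, segment_label: str | None = None) -> int:
        return sum(
            1
            for e in self.events
            if e.event_class == event_class
            and (segment_label is None or e.segment_label == segment_label)
        )

    def in_segment(self, label: str, occurrence: int = 0) -> list[StepEvent]:
        idx = [i for i, lab in enumerate(self.protocol_labels) if lab == label]
        if len(idx) <= occurrence:
            return []
        return [e for e in self.events if e.segment_index == idx[occurrence]]


def _binary_segmentation(y: np.ndarray, min_len: int, penalty: float) -> list[int]:
    """Greedy mean-shift change points; returns sorted split indices.

    A split at k divides y[a:b] into y[a:k], y[k:b]; it is kept when the
    within-segment sum-of-squares drops by more than ``penalty``.
    """
    changepoints: list[int] = []
    stack = [(0, len(y))]
    while stack:
        a, b = stack.pop()
        n = b - a
        if n < 2 * min_len:
            continue
        seg = y[a:b]
        c = np.concatenate([[0.0], np.cumsum(seg)])
        total = c[-1]
        k = np.arange(min_len, n - min_len + 1, dtype=float)
        left = c[min_len : n - min_len + 1]
        # cost reduction of splitting at k (constant-mean segments)
        gain = left**2 / k + (total - left) ** 2 / (n - k) - total**2 / n
        j = int(np.argmax(gain))
        if gain[j] > penalty:
            split = a + min_len + j
            changepoints.append(split)
            stack.append((a, split))
            stack.append((split, b))
    return sorted(changepoints)


def _estimate_noise_sd(y: np.ndarray) -> float:
    """Robust noise SD from first differences (steps are sparse outliers)."""
    d = np.diff(y)
    if d.size == 0:
        return 1e-6
    mad = np.median(np.abs(d - np.median(d)))
    return max(mad / 0.6744897501960817 / np.sqrt(2.0), 1e-6)


def _cluster_changepoints(cps: list[int], gap: int) -> list[list[int]]:
    """Group change points closer than ``gap`` samples into one cluster.

    Binary segmentation approximates the finite feedback-settling ramp of a
    single step with a short staircase; each cluster is one physical event.
    """
    clusters: list[list[int]] = []
    for cp in cps:
        if clusters and cp - clusters[-1][-1] < gap:
            clusters[-1].append(cp)
        else:
            clusters.append([cp])
    return clusters


def _plateau_mean(y: np.ndarray, a: int, b: int, skip: int) -> float:
    """Mean of plateau y[a:b], skipping up to ``skip`` settle-ramp samples."""
    lo = a + min(skip, max((b - a) // 2, 0))
    return float(np.mean(y[lo:b]))


def _plateaus_with_pruning(
    y: np.ndarray, clusters: list[list[int]], skip: int, min_step_nm: float
) -> tuple[list[int], list[float], float]:
    """Plateau levels between change-point clusters, pruning spurious ones.

    Plateau i runs from the end of cluster i-1 to the start of cluster i, so
    settling ramps lie inside clusters, not plateaus.  Clusters whose level
    jump stays below ``min_step_nm`` (feedback-ramp residues, noise) are
    removed iteratively so they do not fragment genuine plateaus; removal
    order is smallest |jump| first.  Returns event start indices, jump
    sizes, and the final plateau level.
    """
    clusters = list(clusters)
    while True:
        edges_a = [0] + [c[-1] for c in clusters]
        edges_b = [c[0] for c in clusters] + [len(y)]
        means = [
            _plateau_mean(y, a, b, skip if i > 0 else 0)
            for i, (a, b) in enumerate(zip(edges_a, edges_b))
        ]
        if not clusters:
            return [], [], means[-1]
        jumps = np.diff(means)
        weakest = int(np.argmin(np.abs(jumps)))
        if abs(jumps[weakest]) >= min_step_nm:
            return [c[0] for c in clusters], list(jumps), means[-1]
        del clusters[weakest]


def detect_steps(
    trajectory,
    min_step_nm: float = 5.0,
    min_dwell_s: float = 0.004,
    penalty_factor: float = 10.0,
    settle_mask_s: float | None = None,
) -> EventSet:
    """Segment a trajectory into plateaus and classify the upward jumps.

    Each constant-force segment is processed independently; the first
    ``settle_mask_s`` (default 4x the feedback settling time, at least
    8 ms) after every force change is masked to suppress spurious elastic
    steps.  Change points closer than ``min_dwell_s`` are coalesced into a
    single event (the feedback ramp of one step, or physically unresolvable
    near-simultaneous steps), and plateau means skip the settle ramp, so
    event sizes are differences between stabilized plateau levels.  Jumps
    >= ``min_step_nm`` become events.
    """
    if min_step_nm <= 0 or min_dwell_s <= 0:
        raise ValueError("thresholds must be > 0")
    t = np.asarray(trajectory.time_s)
    x = np.asarray(trajectory.extension_nm)
    if t.size == 0:
        raise ValueError("empty trajectory")
    dt_all = np.diff(t)
    if t.size > 1 and (np.any(dt_all <= 0) or np.ptp(dt_all) > 1e-6 * np.median(dt_all) + 1e-12):
        raise ValueError("time axis must be uniform and strictly increasing")
    dt = float(dt_all[0]) if t.size > 1 else 1.0

    protocol: ForceProtocol = trajectory.protocol
    tau = getattr(trajectory, "feedback_tau_s", 0.002)
    if settle_mask_s is None:
        settle_mask_s = max(4.0 * tau, 0.008)
    min_len = max(int(round(min_dwell_s / dt)), 1)
    skip = int(np.ceil(3.0 * tau / dt)) if tau > 0 else 0

    bounds = protocol.boundaries_s()
    labels = protocol.labels()
    events: list[StepEvent] = []
    segment_levels: dict[int, float] = {}

    for si, label in enumerate(labels):
        i0 = int(np.searchsorted(t, bounds[si] + settle_mask_s, side="left"))
        i1 = int(np.searchsorted(t, bounds[si + 1] - 1e-12, side="left"))
        if i1 - i0 < 2 * min_len:
            continue
        y = x[i0:i1]
        sd = _estimate_noise_sd(y)
        penalty = max(penalty_factor * sd**2 * np.log(len(y)), 1e-9)
        cps = _binary_segmentation(y, min_len, penalty)
        ramp = int(np.ceil(1.0 * tau / dt)) if tau > 0 else 0
        clusters = _cluster_changepoints(cps, max(min_len, ramp + 1))
        starts, sizes, level = _plateaus_with_pruning(y, clusters, skip, min_step_nm)
        segment_levels[si] = level
        for start, size in zip(starts, sizes):
            if size < min_step_nm:
                continue
            events.append(
                StepEvent(
                    time_s=float(t[i0 + start]),
                    size_nm=size,
                    event_class=_classify(size, label),
                    segment_label=label,
                    segment_index=si,
                )
            )

    events.sort(key=lambda e: e.time_s)
    try:
        test_idx = protocol.segment_index("test")
        test_force = protocol.segments[test_idx].force_pN
        test_onset = float(bounds[test_idx])
        test_dur = protocol.segments[test_idx].duration_s
    except ValueError:
        test_force, test_onset, test_dur = float("nan"), float("nan"), float("nan")

    accepted = len(events) > 0
    return EventSet(
        events=events,
        trajectory_id=getattr(trajectory, "trajectory_id", ""),
        accepted=accepted,
        rejection_reason="" if accepted else "no events",
        segment_levels=segment_levels,
        compound_name=getattr(trajectory, "compound_name", ""),
        test_force_pN=test_force,
        test_onset_s=test_onset,
        test_duration_s=test_dur,
        protocol_labels=tuple(labels),
    )


def _classify(size_nm: float, segment_label: str) -> str:
    """Size-window classification with segment-phase priority.

    The protocol phase sets the expected event type: in the unfold pulse
    every 11-19 nm step is an unfolding event, and in test/probe pulses the
    11-13 nm overlap between the two windows is resolved toward the
    reduction fingerprint expected there.  Steps outside both windows stay
    unclassified (e.g. two unresolved near-simultaneous cleavages).
    """
    in_unfold = UNFOLD_WINDOW_NM[0] <= size_nm <= UNFOLD_WINDOW_NM[1]
    in_reduction = REDUCTION_WINDOW_NM[0] <= size_nm <= REDUCTION_WINDOW_NM[1]
    if segment_label in ("unfold", "quench"):
        return "unfold" if in_unfold else "unclassified"
    reduction_class = "reform_probe" if segment_label == "probe" else "reduction"
    if in_reduction:
        return reduction_class
    if in_unfold:
        return "unfold"
    return "unclassified"


def filter_kinetics_trace(events: EventSet) -> EventSet:
    """Acceptance filter for two-pulse kinetics recordings.

    Accepted iff 5-8 unfolding events, 5-8 reduction events, and no
    unfolding-class event inside the high-force test pulse.
    """
    n_unfold = events.count("unfold")
    n_red = events.count("reduction")
    reason = ""
    if not events.events:
        reason = "no events"
    elif n_unfold < 5:
        reason = f"fewer than 5 unfolding events ({n_unfold})"
    elif n_unfold > 8:
        reason = f"more than 8 unfolding events ({n_unfold})"
    elif n_red < 5:
        reason = f"fewer than 5 reduction events ({n_red})"
    elif n_red > 8:
        reason = f"more than 8 reduction events ({n_red})"
    elif events.count("unfold", segment_label="test") > 0:
        reason = "unfolding event in the high-force pulse"
    return replace(events, accepted=(reason == ""), rejection_reason=reason)


def filter_reformation_trace(
    events: EventSet, extension_match_tol_nm: float = 10.0
) -> EventSet:
    """Acceptance filter for five-pulse reformation recordings.

    Accepted iff the first high-force pulse shows 5-8 rupture (reduction)
    events and the protein reaches the same total extension in the initial
    and probe pulses within ``extension_match_tol_nm``.
    """
    labels = events.protocol_labels
    if "probe" not in labels:
        raise ValueError("reformation filter requires a probe segment")
    test_idx = labels.index("test")
    probe_idx = labels.index("probe")
    n_rupture = len([e for e in events.in_segment("test") if e.event_class == "reduction"])
    reason = ""
    if n_rupture < 5:
        reason = f"fewer than 5 rupture events in first pulse ({n_rupture})"
    elif n_rupture > 8:
        reason = f"more than 8 rupture events in first pulse ({n_rupture})"
    else:
        lev_test = events.segment_levels.get(test_idx)
        lev_probe = events.segment_levels.get(probe_idx)
        if lev_test is None or lev_probe is None:
            reason = "missing extension level for test or probe pulse"
        elif abs(lev_test - lev_probe) > extension_match_tol_nm:
            reason = (
                "extension mismatch between initial and probe pulses "
                f"({abs(lev_test - lev_probe):.1f} nm)"
            )
    return replace(events, accepted=(reason == ""), rejection_reason=reason)
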