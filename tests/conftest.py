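import numpy as np
import pytest

from clampchem import load_compound_table
from clampchem.core import two_pulse_protocol
from clampchem.detect import EventSet, StepEvent


@pytest.fixture(scope="session")
def table():
    return load_compound_table()


@pytest.fixture(scope="session")
def kinetics_protocol():
    return two_pulse_protocol(350.0, 20.0)


def make_kinetics_eventset(
    reduction_times,
    reduction_sizes=None,
    unfold_times=(0.05, 0.1, 0.15, 0.2, 0.25, 0.3),
    test_onset=0.5,
    test_duration=20.0,
    trajectory_id="synthetic",
    compound_name="l-cysteine",
    force=350.0,
):
    """Hand-built two-pulse EventSet (times in the test pulse are relative
    to its onset); used to exercise kinetics aggregation without running
    detection."""
    if reduction_sizes is None:
        reduction_sizes = [10.0] * len(reduction_times)
    events = [
        StepEvent(t, 15.0, "unfold", "unfold", 0) for t in unfold_times
    ] + [
        StepEvent(test_onset + t, s, "reduction", "test", 1)
        for t, s in sorted(zip(reduction_times, reduction_sizes))
    ]
    events.sort(key=lambda e: e.time_s)
    return EventSet(
        events=events,
        trajectory_id=trajectory_id,
        accepted=True,
        compound_name=compound_name,
        test_force_pN=force,
        test_onset_s=test_onset,
        test_duration_s=test_duration,
        protocol_labels=("unfold", "test"),
    )


def exponential_eventsets(rate, n_traces, seed, n_events=8, test_duration=None):
    """Cohort of synthetic EventSets with exponential reduction times."""
    rng = np.random.default_rng(seed)
    if test_duration is None:
        test_duration = max(8.0 / rate, 5.0)
    out = []
    for i in range(n_traces):
        times = np.sort(rng.exponential(1.0 / rate, size=n_events))
        times = times[times < test_duration]
        if times.size == 0:
            continue
        sizes = rng.normal(10.0, 1.0, size=times.size)
        out.append(
            make_kinetics_eventset(
                times, sizes, trajectory_id=f"exp{i}", test_duration=test_duration
            )
        )
    return out
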