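"""Change-point step detection and trace-acceptance filters."""

from dataclasses import replace

import numpy as np
import pytest

from clampchem.core import two_pulse_protocol, five_pulse_protocol
from clampchem.detect import (
    EventSet,
    StepEvent,
    detect_steps,
    filter_kinetics_trace,
    filter_reformation_trace,
)
from clampchem.simulate import SimulationConfig, Trajectory, child_seed, simulate_kinetics_trace

from conftest import make_kinetics_eventset


def staircase_trajectory(step_times, step_sizes, duration=3.0, fs=1000.0, offset=0.0):
    """Hand-built noiseless single-segment staircase."""
    proto = two_pulse_protocol(350.0, duration - 0.5)
    t = np.arange(int(duration * fs)) / fs
    ext = np.full(t.size, offset)
    for when, size in zip(step_times, step_sizes):
        ext[t >= when] += size
    force = np.where(t < 0.5, 150.0, 350.0)
    return Trajectory(
        time_s=t, force_pN=force, extension_nm=ext, true_events=[],
        protocol=proto, compound_name="l-cysteine", seed=0,
        sample_rate_Hz=fs, feedback_tau_s=0.0, trajectory_id="stairs",
    )


class TestDetectSteps:
    def test_noiseless_staircase_recovered_exactly(self):
        times = [0.05, 0.15, 0.25, 0.35, 0.45]
        traj = staircase_trajectory(times, [15.0] * 5)
        es = detect_steps(traj)
        unfolds = [e for e in es.events if e.event_class == "unfold"]
        assert len(unfolds) == 5
        assert all(e.size_nm == pytest.approx(15.0, abs=1e-9) for e in unfolds)
        assert all(abs(e.time_s - t0) <= 0.0011 for e, t0 in zip(unfolds, times))

    def test_flat_trace_yields_empty_rejected_set(self):
        traj = staircase_trajectory([], [])
        es = detect_steps(traj)
        assert es.events == []
        assert not es.accepted
        assert es.rejection_reason == "no events"

    def test_translation_invariance(self):
        times = [0.1, 0.3, 0.8, 1.4]
        a = detect_steps(staircase_trajectory(times, [15, 15, 10, 10]))
        b = detect_steps(staircase_trajectory(times, [15, 15, 10, 10], offset=250.0))
        assert [(e.time_s, round(e.size_nm, 9)) for e in a.events] == [
            (e.time_s, round(e.size_nm, 9)) for e in b.events
        ]

    def test_rejects_bad_inputs(self):
        traj = staircase_trajectory([0.1], [15.0])
        with pytest.raises(ValueError):
            detect_steps(traj, min_step_nm=-1.0)
        broken = replace(traj) if False else traj
        broken.time_s = traj.time_s.copy()
        broken.time_s[100] = broken.time_s[99]  # non-monotonic sample
        with pytest.raises(ValueError):
            detect_steps(broken)

    def test_noiseless_end_to_end_identity(self, table):
        """With zero noise and zero settling, detection reproduces the
        generator's ground truth exactly (sizes/classes; times to 1 sample)
        on traces whose events are resolvable (outside masks, separated,
        chemistry confined to the test pulse)."""
        proto = two_pulse_protocol(350.0, 20.0, unfold_duration_s=1.5)
        cfg = SimulationConfig(
            n_domains=6, unfold_rate_150pN_s=4.0, noise_sd_nm=0.0, feedback_tau_s=0.0
        )
        checked = 0
        for seed in range(60):
            traj = simulate_kinetics_trace(
                table["cysteine-methyl-ester"], proto, replace(cfg, seed=seed)
            )
            tes = sorted(traj.true_events, key=lambda e: e.time_s)
            times = [e.time_s for e in tes]
            if len(times) < 8:
                continue
            resolvable = (
                all(b - a > 0.012 for a, b in zip(times, times[1:]))
                and times[0] > 0.010
                and min(abs(t - 1.5) for t in times) > 0.010
                and all(e.segment_label == "test" for e in tes if e.event_class == "reduction")
            )
            if not resolvable:
                continue
            es = detect_steps(traj)
            assert len(es.events) == len(tes)
            for det, true in zip(es.events, tes):
                assert det.size_nm == pytest.approx(true.size_nm, abs=1e-9)
                assert abs(det.time_s - true.time_s) <= 0.0011
                assert det.event_class == true.event_class
            checked += 1
        assert checked >= 3  # the scan must actually exercise the identity

    def test_noisy_recovery_rate_and_size_error(self, table):
        """>= 95% of resolvable true events recovered with |size error| < 1 nm
        at the instrument noise level (SD 1 nm), and median error < 0.5 nm."""
        proto = two_pulse_protocol(350.0, 20.0, unfold_duration_s=1.5)
        cfg = SimulationConfig(n_domains=6, unfold_rate_150pN_s=4.0)
        recovered, total, errors = 0, 0, []
        for ri in range(25):
            traj = simulate_kinetics_trace(
                table["cysteine-methyl-ester"], proto, replace(cfg, seed=child_seed(77, ri))
            )
            es = detect_steps(traj)
            tes = sorted(traj.true_events, key=lambda e: e.time_s)
            for i, te in enumerate(tes):
                seg0, seg1 = (0.0, 1.5) if te.time_s < 1.5 else (1.5, 21.5)
                if te.time_s - seg0 < 0.009 or seg1 - te.time_s < 0.006:
                    continue
                if min(abs(te.time_s - o.time_s) for j, o in enumerate(tes) if j != i) < 0.008:
                    continue
                total += 1
                match = [d for d in es.events if abs(d.time_s - te.time_s) < 0.01]
                if match and abs(match[0].size_nm - te.size_nm) < 1.0:
                    recovered += 1
                    errors.append(abs(match[0].size_nm - te.size_nm))
        assert total > 200
        assert recovered / total >= 0.95
        assert np.median(errors) < 0.5


def _five_pulse_eventset(n_rupture=6, n_probe=3, level_test=150.0, level_probe=150.0):
    events = (
        [StepEvent(0.05 + 0.05 * i, 15.0, "unfold", "unfold", 0) for i in range(6)]
        + [StepEvent(0.6 + 0.3 * i, 10.0, "reduction", "test", 1) for i in range(n_rupture)]
        + [StepEvent(14.1 + 0.05 * i, 15.0, "unfold", "unfold", 3) for i in range(6)]
        + [StepEvent(14.7 + 0.3 * i, 10.0, "reform_probe", "probe", 4) for i in range(n_probe)]
    )
    return EventSet(
        events=sorted(events, key=lambda e: e.time_s),
        trajectory_id="fp",
        accepted=True,
        segment_levels={1: level_test, 4: level_probe},
        compound_name="mesna",
        test_force_pN=350.0,
        test_onset_s=0.5,
        test_duration_s=5.0,
        protocol_labels=("unfold", "test", "quench", "unfold", "probe"),
    )


class TestFilters:
    def test_kinetics_accepts_well_formed_trace(self):
        es = make_kinetics_eventset([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = filter_kinetics_trace(es)
        assert out.accepted and out.rejection_reason == ""

    @pytest.mark.parametrize(
        "n_unfold, n_red, fragment",
        [(6, 4, "reduction"), (4, 6, "unfolding"), (9, 6, "unfolding"), (6, 9, "reduction")],
    )
    def test_kinetics_rejects_bad_counts(self, n_unfold, n_red, fragment):
        es = make_kinetics_eventset(
            [0.5 * (i + 1) for i in range(n_red)],
            unfold_times=[0.04 * (i + 1) for i in range(n_unfold)],
        )
        out = filter_kinetics_trace(es)
        assert not out.accepted
        assert fragment in out.rejection_reason

    def test_kinetics_rejects_unfold_in_high_force_pulse(self):
        es = make_kinetics_eventset([1.0, 2.0, 3.0, 4.0, 5.0])
        es.events.append(StepEvent(7.0, 15.0, "unfold", "test", 1))
        out = filter_kinetics_trace(es)
        assert not out.accepted
        assert "high-force" in out.rejection_reason

    def test_filters_idempotent(self):
        es = make_kinetics_eventset([1.0, 2.0, 3.0, 4.0, 5.0])
        once = filter_kinetics_trace(es)
        twice = filter_kinetics_trace(once)
        assert (once.accepted, once.rejection_reason) == (twice.accepted, twice.rejection_reason)
        fp = _five_pulse_eventset()
        once = filter_reformation_trace(fp)
        twice = filter_reformation_trace(once)
        assert (once.accepted, once.rejection_reason) == (twice.accepted, twice.rejection_reason)

    def test_reformation_accepts_matching_extension(self):
        out = filter_reformation_trace(_five_pulse_eventset(level_test=150.0, level_probe=145.0))
        assert out.accepted

    def test_reformation_rejects_few_ruptures(self):
        out = filter_reformation_trace(_five_pulse_eventset(n_rupture=4))
        assert not out.accepted and "5" in out.rejection_reason

    def test_reformation_rejects_extension_mismatch(self):
        out = filter_reformation_trace(_five_pulse_eventset(level_probe=110.0))
        assert not out.accepted and "mismatch" in out.rejection_reason

    def test_reformation_requires_probe_segment(self):
        es = make_kinetics_eventset([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError):
            filter_reformation_trace(es)
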