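"""Event detection, tracing, censoring and rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gasport.event_tracing import (
    EventThresholds,
    detect_events,
    rate_summary,
    summarize_events,
)
from gasport.io_model import RelativeTrajectory
from gasport.synthetic_gas import scripted_fixture


def _traj_from_distances(distances, stride=10.0):
    """A 1-molecule trajectory along +x with the given anchor distances."""
    d = np.asarray(distances, dtype=float)
    pos = np.zeros((len(d), 1, 3))
    pos[:, 0, 0] = d
    return RelativeTrajectory(
        times=np.arange(len(d)) * stride,
        molecule_ids=["m"],
        positions=pos,
        stride=stride,
    )


def test_worked_example_entry_and_exit(thresholds):
    traj = _traj_from_distances([25, 18, 10, 5, 4, 9, 21])
    events = detect_events(traj, thresholds)
    assert len(events) == 2
    entry, exit_ = events
    assert entry.direction == "entry"
    assert (entry.t_outer, entry.t_inner) == (0.0, 30.0)
    assert entry.duration == pytest.approx(0.03)
    assert exit_.direction == "exit"
    assert (exit_.t_inner, exit_.t_outer) == (40.0, 60.0)
    assert entry.min_distance == pytest.approx(4.0)
    assert entry.dwell_id == exit_.dwell_id
    assert not entry.censored and not exit_.censored


def test_no_approach_no_events(thresholds, far_trajectory):
    assert detect_events(far_trajectory, thresholds) == []


def test_trajectory_starting_inside_is_censored(thresholds):
    traj = _traj_from_distances([5, 4, 9, 21, 25])
    events = detect_events(traj, thresholds)
    entry, exit_ = events
    assert entry.censored and entry.duration is None
    assert not exit_.censored
    assert exit_.t_outer == 30.0


def test_rattling_at_cutoff_is_one_dwell(thresholds):
    # two sub-6 dwells separated by an excursion to 15 Å (< r_outer): one event
    traj = _traj_from_distances([25, 5, 15, 5, 25])
    events = detect_events(traj, thresholds)
    assert len(events) == 2
    # but separated by an outer-shell crossing: two events
    traj2 = _traj_from_distances([25, 5, 22, 5, 25])
    assert len(detect_events(traj2, thresholds)) == 4


def test_scripted_fixture_events(dip_trajectory, thresholds):
    events = detect_events(dip_trajectory, thresholds)
    assert [e.direction for e in events] == ["entry", "exit"]


def test_published_rate_arithmetic():
    s = rate_summary(249, 10.0, 100)
    assert s["events_per_us"] == pytest.approx(24.9)
    assert s["interevent_ns"] == pytest.approx(40.16, abs=0.01)
    assert s["per_molecule_interval_us"] == pytest.approx(4.016, abs=0.001)


def test_mean_entry_time(thresholds):
    # durations 1 ns and 3 ns from two molecules
    t1 = _traj_from_distances([25] + [19] * 99 + [5, 25])
    t2 = _traj_from_distances([25] + [19] * 299 + [5, 25])
    pos = np.zeros((302, 2, 3))
    pos[: t1.n_frames, 0, 0] = t1.positions[:, 0, 0]
    pos[t1.n_frames :, 0, 0] = 25.0
    pos[:, 1, 0] = t2.positions[:, 0, 0]
    traj = RelativeTrajectory(
        times=np.arange(302) * 10.0, molecule_ids=["a", "b"], positions=pos, stride=10.0
    )
    events = detect_events(traj, thresholds)
    entries = [e for e in events if e.direction == "entry"]
    assert sorted(e.duration for e in entries) == [1.0, 3.0]
    summary = summarize_events(events, total_time_us=3.01e-3, n_molecules=2)
    assert summary["mean_entry_ns"] == pytest.approx(2.0)


def test_zero_events_flagged():
    s = summarize_events([], total_time_us=1.0, n_molecules=10)
    assert s["n_events"] == 0 and s["zero_events"]
    assert s["events_per_us"] == 0.0


def test_invalid_thresholds_rejected():
    with pytest.raises(ValueError):
        EventThresholds(r_inner=20.0, r_outer=6.0)


def test_entry_exit_pairing(thresholds):
    rng = np.random.default_rng(5)
    d = np.abs(25 + np.cumsum(rng.normal(0, 3, size=400)))
    events = detect_events(_traj_from_distances(d), thresholds)
    n_entries = sum(e.direction == "entry" for e in events)
    n_exits = sum(e.direction == "exit" for e in events)
    assert n_entries == n_exits  # each dwell emits exactly one of each


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_threshold_monotonicity(seed):
    """Raising r_inner never decreases the dwell count."""
    rng = np.random.default_rng(seed)
    d = np.abs(15 + np.cumsum(rng.normal(0, 2.5, size=200)))
    traj = _traj_from_distances(d)
    counts = []
    for r_inner in (4.0, 6.0, 8.0):
        events = detect_events(traj, EventThresholds(r_inner, 20.0, 10.0))
        counts.append(sum(e.direction == "entry" for e in events))
    assert counts == sorted(counts)
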