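"""Contact frequencies, trapped filter, pathway labels, overlap statistics."""

import numpy as np
import pandas as pd
import pytest

from gasport.contact_pathways import (
    PathwayDefinition,
    aggregate_table,
    classify_all,
    classify_pathway,
    contact_frequencies,
    overlap_and_samepath,
    trapped_filter,
)
from gasport.event_tracing import EventRecord, EventThresholds, detect_events
from gasport.io_model import EnvironmentModel, RelativeTrajectory, Residue


def _line_traj(xs, stride=10.0):
    pos = np.zeros((len(xs), 1, 3))
    pos[:, 0, 0] = xs
    return RelativeTrajectory(
        times=np.arange(len(xs)) * stride, molecule_ids=["m"], positions=pos,
        stride=stride,
    )


def _env(atoms: dict[str, tuple]):
    return EnvironmentModel([Residue(rid, rid, np.array([xyz])) for rid, xyz in atoms.items()])


def _event(span, direction="entry", mol="m", dwell=0):
    return EventRecord(
        molecule_id=mol, direction=direction, dwell_id=dwell,
        t_outer=span[0] * 10.0, t_inner=span[1] * 10.0,
        min_distance=5.0, frame_span=span,
    )


def test_contact_cutoff_boundary():
    traj = _line_traj([10.0, 10.0, 10.0])
    env = _env({"NEAR": (13.0, 0, 0), "FAR": (13.6, 0, 0)})
    profile = contact_frequencies([_event((0, 2))], traj, env, cutoff=3.5)
    residues = set(profile.per_pair["residue_id"])
    assert residues == {"NEAR"}  # 3.0 Å contact, 3.6 Å is not


def test_contact_frequency_units():
    # 120 contact frames in a 10 ns span at 10 ps stride → 12 contacts/ns
    n = 1000
    xs = np.full(n, 30.0)
    xs[:120] = 10.0
    traj = _line_traj(xs)
    env = _env({"R1": (10.0, 0, 0)})
    profile = contact_frequencies([_event((0, n - 1))], traj, env)
    row = profile.per_pair.iloc[0]
    assert row["n_frames"] == 120
    assert row["frequency"] == pytest.approx(12.0)
    assert row["fraction"] == pytest.approx(0.12)


def test_trapped_filter_removes_only_dominant_pairs():
    traj = _line_traj([10.0] * 100)
    env = _env({"STICKY": (10.0, 0, 0), "BRIEF": (200.0, 0, 0)})
    # STICKY in contact all frames (fraction 1.0); BRIEF never
    profile = contact_frequencies([_event((0, 99))], traj, env)
    starred = trapped_filter(profile, threshold=0.75)
    assert set(profile.per_pair["residue_id"]) == {"STICKY"}
    assert starred.per_pair.empty  # the >75% pair is removed, event retained
    assert starred.trapped_filtered


def test_trapped_filter_below_threshold_kept():
    n = 100
    xs = np.full(n, 30.0)
    xs[:70] = 10.0
    traj = _line_traj(xs)
    env = _env({"R1": (10.0, 0, 0)})
    profile = contact_frequencies([_event((0, n - 1))], traj, env)
    starred = trapped_filter(profile, threshold=0.75)
    assert len(starred.per_pair) == 1  # 70% < 75%: kept


def test_trapped_filter_two_dominant_pairs_both_removed():
    traj = _line_traj([10.0] * 100)
    env = _env({"A": (10.0, 1.0, 0), "B": (10.0, -1.0, 0)})
    profile = contact_frequencies([_event((0, 99))], traj, env)
    starred = trapped_filter(profile)
    assert len(profile.per_pair) == 2
    assert starred.per_pair.empty


def test_starred_frequencies_never_exceed_unfiltered():
    rng = np.random.default_rng(8)
    xs = np.where(rng.random(400) < 0.5, 10.0, 30.0)
    traj = _line_traj(xs)
    env = _env({"R1": (10.0, 0, 0), "R2": (10.0, 2.0, 0), "R3": (28.0, 0, 0)})
    events = [_event((0, 199)), _event((200, 399), dwell=1)]
    profile = contact_frequencies(events, traj, env)
    starred = trapped_filter(profile)
    raw = aggregate_table(profile, floor=0.0).set_index(["pathway", "direction", "residue_id"])
    filt = aggregate_table(starred, floor=0.0).set_index(["pathway", "direction", "residue_id"])
    assert set(filt.index) <= set(raw.index)  # no new residues appear
    for idx in filt.index:
        assert filt.loc[idx, "frequency"] <= raw.loc[idx, "frequency"] + 1e-12


def test_classification_against_well_ground_truth():
    from gasport.synthetic_gas import SyntheticSystem, WellSpec, scripted_fixture

    system = SyntheticSystem(
        box_half_edge=30.0,
        wells=(
            WellSpec("W1", (12.0, 0.0, 0.0), 3.0, 2.0, n_lining=16),
            WellSpec("W2", (-12.0, 0.0, 0.0), 3.0, 2.0, n_lining=16),
        ),
    )
    env = system.environment()
    # one molecule enters through W1's corridor, another through W2's
    traj = scripted_fixture(
        [
            (0.0, "a", (25.0, 0, 0)), (100.0, "a", (4.0, 0, 0)), (200.0, "a", (25.0, 0, 0)),
            (0.0, "b", (-25.0, 0, 0)), (100.0, "b", (-4.0, 0, 0)), (200.0, "b", (-25.0, 0, 0)),
        ],
        save_stride=10.0,
    )
    events = detect_events(traj, EventThresholds(6.0, 20.0, 10.0))
    profile = contact_frequencies(events, traj, env)
    defs = [
        PathwayDefinition("W1", frozenset(env.regions["W1"]), 0),
        PathwayDefinition("W2", frozenset(env.regions["W2"]), 1),
    ]
    classify_all(events, profile, defs)
    for ev in events:
        assert ev.pathway_label == ("W1" if ev.molecule_id == "a" else "W2")


def test_classification_tie_and_unassigned():
    traj = _line_traj([10.0] * 10)
    env = _env({"A1": (10.0, 1.0, 0), "B1": (10.0, -1.0, 0), "C1": (100.0, 0, 0)})
    ev = _event((0, 9))
    profile = contact_frequencies([ev], traj, env)
    defs = [
        PathwayDefinition("PB", frozenset({"B1"}), priority=1),
        PathwayDefinition("PA", frozenset({"A1"}), priority=0),
    ]
    # equal contact mass on both signatures: lower priority rank wins
    assert classify_pathway(ev, profile, defs) == "PA"
    only_c = [PathwayDefinition("PC", frozenset({"C1"}), 0)]
    assert classify_pathway(ev, profile, only_c) == "unassigned"
    with pytest.raises(ValueError):
        classify_pathway(ev, profile, [])


def test_classification_permutation_invariant():
    traj = _line_traj([10.0] * 10)
    env = _env({"A1": (10.0, 1.0, 0), "A2": (10.0, -1.0, 0)})
    ev = _event((0, 9))
    profile = contact_frequencies([ev], traj, env)
    d1 = [PathwayDefinition("P", frozenset({"A1", "A2"}), 0)]
    d2 = [PathwayDefinition("P", frozenset({"A2", "A1"}), 0)]
    assert classify_pathway(ev, profile, d1) == classify_pathway(ev, profile, d2)


def _labeled(mol, dwell, direction, t0, t1, label):
    ev = _event((int(t0 // 10), int(t1 // 10)), direction, mol, dwell)
    ev.pathway_label = label
    return ev


def test_overlap_and_samepath_counts():
    events = [
        _labeled("a", 0, "entry", 0, 100, "P1"),
        _labeled("a", 0, "exit", 100, 200, "P1"),
        _labeled("b", 1, "entry", 50, 150, "P1"),   # overlaps both of a's events
        _labeled("b", 1, "exit", 150, 250, "P2"),
        _labeled("c", 2, "entry", 300, 400, "P2"),  # disjoint from everything
    ]
    overlap, samepath = overlap_and_samepath(events)
    assert overlap.loc["P1", "P1"] == 2
    assert overlap.loc["P1", "P2"] == 1  # a's exit vs b's exit
    assert overlap.loc["P2", "P2"] == 0
    sp = samepath.set_index("pathway")
    assert sp.loc["P1", "same_path_pct"] == pytest.approx(50.0)  # a same, b switched


def test_all_same_path_is_100_pct():
    events = []
    for i in range(4):
        events.append(_labeled(f"m{i}", i, "entry", 1000 * i, 1000 * i + 100, "Pr"))
        events.append(_labeled(f"m{i}", i, "exit", 1000 * i + 100, 1000 * i + 200, "Pr"))
    _, samepath = overlap_and_samepath(events)
    row = samepath.set_index("pathway").loc["Pr"]
    assert row["same_path_pct"] == pytest.approx(100.0)
    assert row["n_dwells"] == 4
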