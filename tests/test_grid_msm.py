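"""Grid discretization, MSM estimation, validation and reduction."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from gasport.event_tracing import EventThresholds, detect_events
from gasport.grid_msm import (
    NULL_STATE,
    DiscreteTrajectory,
    GridSpec,
    MSMModel,
    assign_states,
    count_transitions,
    estimate_msm,
    implied_timescales,
    reduce_milestoning,
    restrict_to_events,
    sample_bayesian,
    select_source_sink,
    stationary_distribution,
)
from gasport.synthetic_gas import scripted_fixture
from gasport.validation import sample_markov_chain


def _chain_dtraj(states, stride=100.0, n_states=None):
    states = np.asarray(states)
    return DiscreteTrajectory(
        states=states[:, None],
        times=np.arange(len(states)) * stride,
        stride=stride,
        molecule_ids=["m"],
        n_states=n_states or int(states.max()) + 1,
    )


def test_default_grid_capacity():
    assert GridSpec().n_states == 40**3 == 64_000


def test_nearest_point_rounding():
    g = GridSpec()
    s = g.assign(np.array([0.4, -0.3, 0.2]))
    np.testing.assert_array_equal(g.state_coords(np.array([s]))[0], [0.0, 0.0, 0.0])


def test_wrap_modes():
    gp = GridSpec(wrap_mode="periodic")
    gc = GridSpec(wrap_mode="clamp")
    p = np.array([25.0, 0.0, 0.0])
    np.testing.assert_array_equal(gp.state_coords(np.array([gp.assign(p)]))[0], [-15, 0, 0])
    np.testing.assert_array_equal(gc.state_coords(np.array([gc.assign(p)]))[0], [20, 0, 0])
    assert gc.n_states == 41**3


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 10_000))
def test_grid_bijectivity(seed):
    """Grid points map to state ids and back exactly."""
    rng = np.random.default_rng(seed)
    g = GridSpec(spacing=1.0, half_edge=20.0)
    pts = rng.integers(-20, 20, size=(50, 3)).astype(float)
    states = g.assign(pts)
    np.testing.assert_array_equal(g.state_coords(states), pts)


def test_sliding_window_counts():
    cm = count_transitions(_chain_dtraj([0, 0, 1, 1]), lag=100.0)
    np.testing.assert_array_equal(cm.counts.toarray(), [[1, 1], [0, 1]])


def test_count_conservation():
    rng = np.random.default_rng(3)
    states = rng.integers(0, 5, size=(200, 3))
    states[rng.random(states.shape) < 0.2] = NULL_STATE
    dtraj = DiscreteTrajectory(
        states=states, times=np.arange(200.0), stride=1.0,
        molecule_ids=list("abc"), n_states=5,
    )
    lagf = 2
    cm = count_transitions(dtraj, lag=float(lagf))
    expected = sum(
        np.sum((states[:-lagf, c] != NULL_STATE) & (states[lagf:, c] != NULL_STATE))
        for c in range(3)
    )
    assert cm.counts.sum() == expected


def test_mle_is_row_normalization():
    dtraj = _chain_dtraj([0, 1, 0, 0, 1, 0, 1, 1, 0, 0, 0])
    model = estimate_msm(dtraj, lag=100.0)
    C = count_transitions(dtraj, 100.0).counts.toarray()
    np.testing.assert_allclose(
        model.transition_matrix.toarray(), C / C.sum(axis=1, keepdims=True)
    )
    rows = model.transition_matrix.sum(axis=1)
    np.testing.assert_allclose(np.asarray(rows).ravel(), 1.0, atol=1e-12)


def test_symmetric_stationary_distribution():
    T = sp.csr_matrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
    np.testing.assert_allclose(stationary_distribution(T), [0.5, 0.5])


def test_stationary_is_left_eigenvector():
    rng = np.random.default_rng(7)
    T = rng.random((6, 6))
    T /= T.sum(axis=1, keepdims=True)
    pi = stationary_distribution(sp.csr_matrix(T))
    np.testing.assert_allclose(pi @ T, pi, atol=1e-10)
    assert pi.sum() == pytest.approx(1.0)


def test_restrict_to_events(dip_trajectory, thresholds):
    grid = GridSpec(spacing=1.0, half_edge=30.0, wrap_mode="clamp")
    dtraj = assign_states(dip_trajectory, grid)
    assert restrict_to_events(dtraj, []).states.min() == NULL_STATE
    assert (restrict_to_events(dtraj, []).states == NULL_STATE).all()
    events = detect_events(dip_trajectory, thresholds)
    kept = restrict_to_events(dtraj, events)
    # the traced spans cover the full dip here
    inside = (dip_trajectory.times >= 0) & (dip_trajectory.times <= 60)
    assert ((kept.states[:, 0] != NULL_STATE) == inside).all()


def test_restrict_overlapping_spans_union():
    traj = scripted_fixture(
        [(0.0, "a", (25.0, 0, 0)), (30.0, "a", (4.0, 0, 0)), (60.0, "a", (25.0, 0, 0)),
         (0.0, "b", (30.0, 0, 0)), (60.0, "b", (31.0, 0, 0))],
        save_stride=10.0,
    )
    grid = GridSpec(spacing=1.0, half_edge=31.0, wrap_mode="clamp")
    dtraj = assign_states(traj, grid)
    events = detect_events(traj, EventThresholds())
    kept = restrict_to_events(dtraj, events)
    a = traj.molecule_ids.index("a")
    b = traj.molecule_ids.index("b")
    assert (kept.states[:, a] != NULL_STATE).all()
    assert (kept.states[:, b] == NULL_STATE).all()


def test_implied_timescale_closed_form():
    T = np.array([[0.95, 0.05], [0.05, 0.95]])  # λ₂ = 0.9
    states = sample_markov_chain(T, 100_000, seed=0)
    its = implied_timescales(_chain_dtraj(states), lags=[100.0, 200.0], k=1)
    assert its.timescales[0, 0] == pytest.approx(-100.0 / np.log(0.9), rel=0.05)


def test_unit_modulus_eigenvalue_divergent_timescale():
    # deterministic period-2 chain: |λ₂| = 1, the timescale diverges
    dtraj = _chain_dtraj([0, 1] * 50, n_states=2)
    its = implied_timescales(dtraj, lags=[100.0, 200.0], k=1)
    assert np.isinf(its.timescales[0, 0])


def test_bayesian_posterior_concentration():
    dtraj = _chain_dtraj([0] * 1001, n_states=1)
    C = sp.csr_matrix(np.array([[1000.0, 0.0], [1.0, 1.0]]))
    from gasport.grid_msm import CountMatrix

    cm = CountMatrix(counts=C, lag=100.0, stride=100.0)
    samples = sample_bayesian(cm, n_samples=400, seed=0)
    t11 = np.array([s.transition_matrix[0, 0] for s in samples])
    assert np.quantile(t11, 0.025) > 0.99


def test_bayesian_prior_mean():
    C = sp.csr_matrix(np.array([[1.0, 1.0], [1.0, 1.0]]))
    from gasport.grid_msm import CountMatrix

    cm = CountMatrix(counts=C, lag=100.0, stride=100.0)
    samples = sample_bayesian(cm, n_samples=6000, seed=1)
    mean = np.mean([s.transition_matrix[0, 0] for s in samples])
    assert mean == pytest.approx((1 + 0.5) / 3, abs=0.01)


def test_bayesian_seed_reproducible():
    C = sp.csr_matrix(np.array([[5.0, 2.0], [3.0, 4.0]]))
    from gasport.grid_msm import CountMatrix

    cm = CountMatrix(counts=C, lag=100.0, stride=100.0)
    a = sample_bayesian(cm, n_samples=5, seed=42)
    b = sample_bayesian(cm, n_samples=5, seed=42)
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(
            ma.transition_matrix.toarray(), mb.transition_matrix.toarray()
        )
    rows = np.vstack([np.asarray(m.transition_matrix.sum(axis=1)).ravel() for m in a])
    np.testing.assert_allclose(rows, 1.0, atol=1e-12)


def test_milestoning_last_core_rule():
    dtraj = _chain_dtraj([0, 5, 6, 1, 5, 0], n_states=8)
    reduced = reduce_milestoning(dtraj, [np.array([0]), np.array([1])])
    np.testing.assert_array_equal(reduced.states[:, 0], [0, 0, 0, 1, 1, 0])
    assert reduced.n_states == 2


def test_milestoning_no_core_visit_all_null():
    dtraj = _chain_dtraj([5, 6, 7], n_states=8)
    reduced = reduce_milestoning(dtraj, [np.array([0]), np.array([1])])
    assert (reduced.states == NULL_STATE).all()


def test_milestoning_overlapping_cores_rejected():
    dtraj = _chain_dtraj([0, 1], n_states=3)
    with pytest.raises(ValueError, match="overlap"):
        reduce_milestoning(dtraj, [np.array([0, 1]), np.array([1, 2])])


def test_select_source_sink_thresholds(thresholds):
    traj = scripted_fixture(
        [(0.0, "m", (25.0, 0, 0)), (200.0, "m", (5.0, 0, 0)), (400.0, "m", (25.0, 0, 0))],
        save_stride=10.0,
    )  # 1 Å per frame: visits every integer distance 25..5..25
    grid = GridSpec(spacing=1.0, half_edge=30.0, wrap_mode="clamp")
    dtraj = assign_states(traj, grid)
    events = detect_events(traj, thresholds)
    source, sink = select_source_sink(dtraj, events, r_sink=6.7, r_source=22.0)
    sink_d = grid.state_distances(sink)
    assert (sink_d < 6.7).all()
    # (6,0,0) is a sink state, (7,0,0) is not
    assert grid.assign(np.array([6.0, 0, 0])) in set(sink.tolist())
    assert grid.assign(np.array([7.0, 0, 0])) not in set(sink.tolist())
    # entry and exit cross 22 Å at the same grid point on this symmetric path
    assert len(source) == 1


def test_validate_msm_combines_its_and_ck():
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    dtraj = _chain_dtraj(sample_markov_chain(T, 20_000, seed=2))
    from gasport.grid_msm import validate_msm

    its, ck = validate_msm(dtraj, lags=[100.0, 200.0], ck_steps=(1, 2, 3),
                           n_samples=50, seed=0)
    assert its.timescales.shape[0] == 2
    assert np.isfinite(its.timescales[0, 0])
    assert ck.predicted.shape == (3, 2)
    assert ck.passed  # exactly Markovian data


def test_lag_must_be_multiple_of_stride():
    with pytest.raises(ValueError):
        count_transitions(_chain_dtraj([0, 1, 0]), lag=150.0)


def test_empty_counts_rejected():
    dtraj = DiscreteTrajectory(
        states=np.full((5, 1), NULL_STATE), times=np.arange(5.0), stride=1.0,
        molecule_ids=["m"], n_states=3,
    )
    with pytest.raises(ValueError, match="[Ee]mpty|no states"):
        estimate_msm(dtraj, lag=1.0)
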