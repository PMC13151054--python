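"""End-to-end validation suites on synthetic systems with known kinetics.

Each function builds its inputs from scratch (simulation or closed form),
runs the package's own machinery, and returns plain dictionaries of
measured versus expected quantities.  They are shared between the test
suite and the acceptance script so both report the same computations.

Study conditions (fixed, not tuning knobs):

* shell check — free diffusion, D = 1 Å²/ps, absorbing sphere a = 6 Å,
  reflecting sphere b = 20 Å, start on the outer sphere, 10⁴ walkers;
* two-well system — 12 Å half-edge box, two smooth wells of depth 4 and
  3 kT (radius 4 Å) flanking a 4 Å catalytic sink, D = 1 Å²/ps;
* equilibrium recovery — one 1 kT well in a 10 Å half-edge box, 10⁶ saved
  frames on a 2 Å grid.
"""

from __future__ import annotations

import numpy as np

from .diffusion_msd import msd_alpha
from .grid_msm import (
    DiscreteTrajectory,
    GridSpec,
    assign_states,
    chapman_kolmogorov,
    estimate_msm,
    implied_timescales,
    reduce_milestoning,
)
from .kinetics_tpt import compute_mfpt, compute_tpt_rate
from .synthetic_gas import (
    BrownianParams,
    SyntheticSystem,
    WellSpec,
    boltzmann_reference,
    brute_force_mfpt,
    shell_mfpt_analytic,
    simulate_brownian,
)

__all__ = [
    "shell_mfpt_check",
    "two_well_system",
    "two_well_kinetics_check",
    "equilibrium_recovery_check",
    "markov_chain_ck_check",
    "sample_markov_chain",
]


def shell_mfpt_check(seed: int = 0, n_events: int = 10_000, dt: float = 0.005) -> dict:
    """Free-diffusion first passage versus the closed-form shell MFPT.

    Absorbing sphere a = 6 Å, reflecting sphere b = 20 Å, start at r0 = b,
    D = 1 Å²/ps.  The analytic value is ≈ 250.4 ps.
    """
    system = SyntheticSystem(box_half_edge=20.0, sink_radius=6.0)
    params = BrownianParams(n_molecules=1, n_steps=1, dt=dt, seed=seed)
    res = brute_force_mfpt(
        system, params, source_radius=20.0, sink_radius=6.0,
        n_events=n_events, outer_boundary="sphere",
    )
    analytic = shell_mfpt_analytic(1.0, 6.0, 20.0, 20.0)
    return {
        "analytic_ps": analytic,
        "sampled_ps": res.mean,
        "se_ps": res.se,
        "n_events": n_events,
        "within_2se": abs(res.mean - analytic) <= 2 * res.se,
    }


def two_well_system() -> SyntheticSystem:
    """The standard synthetic two-well validation system."""
    wells = (
        WellSpec("W1", (7.0, 0.0, 0.0), radius=4.0, depth=4.0),
        WellSpec("W2", (-7.0, 0.0, 0.0), radius=4.0, depth=3.0),
    )
    return SyntheticSystem(box_half_edge=12.0, wells=wells, sink_radius=4.0)


def two_well_kinetics_check(
    seed: int = 0,
    lag: float = 2.0,
    n_events: int = 10_000,
    n_molecules: int = 200,
    n_steps: int = 500_000,
) -> dict:
    """MSM/TPT kinetics versus brute-force first passage on the two-well system.

    A lag-τ MSM observes first passage at time resolution τ, so the matching
    oracle checks absorption at the same interval (same integrator, same
    box reflection).  Source: the 10 Å shell; sink: the 4 Å catalytic zone.
    Also returns the milestoning-reduced inter-well MFPT against the
    full-state model, and the MSD subdiffusion exponent of the trapped run.
    """
    system = two_well_system()
    bf = brute_force_mfpt(
        system,
        BrownianParams(n_molecules=1, n_steps=1, dt=0.01, seed=seed),
        source_radius=10.0,
        sink_radius=4.0,
        n_events=n_events,
        outer_boundary="box",
        absorb_interval=lag,
    )
    traj = simulate_brownian(
        system,
        BrownianParams(
            n_molecules=n_molecules, n_steps=n_steps, dt=0.01,
            save_stride=1.0, seed=seed + 1,
        ),
    )
    grid = GridSpec(spacing=1.0, half_edge=12.0, wrap_mode="clamp")
    dtraj = assign_states(traj, grid)
    model = estimate_msm(dtraj, lag=lag)
    dist = grid.state_distances(model.active_states)
    sink = model.active_states[dist < 4.0]
    source = model.active_states[np.abs(dist - 10.0) <= 0.5]
    mfpt_msm_ns = compute_mfpt(model, sink, source)
    tpt = compute_tpt_rate(model, source, sink)

    # milestoning: inter-well MFPT, reduced versus full model
    visited = dtraj.visited_states()
    coords = grid.state_coords(visited)
    core_a = visited[np.linalg.norm(coords - np.array([7.0, 0, 0]), axis=1) < 2.0]
    core_b = visited[np.linalg.norm(coords - np.array([-7.0, 0, 0]), axis=1) < 2.0]
    milestoned = reduce_milestoning(dtraj, [core_a, core_b])
    reduced_model = estimate_msm(milestoned, lag=lag)
    mfpt_reduced_ns = compute_mfpt(
        reduced_model, reduced_model.active_states[1:2], reduced_model.active_states[0:1]
    )
    mfpt_full_ab_ns = compute_mfpt(model, core_b, core_a)

    msd = msd_alpha(traj, max_lag=500.0)
    rel_dev = (mfpt_msm_ns * 1000.0 - bf.mean) / bf.mean
    return {
        "lag_ps": lag,
        "brute_force_ps": bf.mean,
        "brute_force_se_ps": bf.se,
        "msm_mfpt_ns": mfpt_msm_ns,
        "tpt_rate_mfpt_ns": tpt.rate_mfpt_ns,
        "rel_dev": rel_dev,
        "milestoning_mfpt_ns": mfpt_reduced_ns,
        "full_ab_mfpt_ns": mfpt_full_ab_ns,
        "msd_alpha": msd.alpha,
        "n_active_states": model.n_active,
        "n_events": n_events,
    }


def equilibrium_recovery_check(seed: int = 0) -> dict:
    """Total variation between the MSM stationary distribution and Boltzmann.

    One 1 kT well (radius 4 Å) in a 10 Å half-edge box; 10⁶ saved frames
    at 2 ps spacing on a 2 Å grid.
    """
    well = WellSpec("W1", (4.0, 0.0, 0.0), radius=4.0, depth=1.0)
    system = SyntheticSystem(box_half_edge=10.0, wells=(well,), sink_radius=2.0)
    params = BrownianParams(
        n_molecules=1000, n_steps=100_000, dt=0.02, save_stride=2.0, seed=seed
    )
    traj = simulate_brownian(system, params)
    grid = GridSpec(spacing=2.0, half_edge=10.0, wrap_mode="clamp")
    dtraj = assign_states(traj, grid)
    model = estimate_msm(dtraj, lag=2.0)
    ids, ref = boltzmann_reference(system, grid)
    ref_map = dict(zip(ids.tolist(), ref))
    pi_map = {int(s): float(p) for s, p in zip(model.active_states, model.pi)}
    keys = set(ref_map) | set(pi_map)
    tv = 0.5 * sum(abs(ref_map.get(k, 0.0) - pi_map.get(k, 0.0)) for k in keys)
    return {
        "total_variation": tv,
        "n_frames": traj.n_frames * traj.n_molecules,
        "n_states": len(keys),
    }


def sample_markov_chain(
    T: np.ndarray, n_steps: int, seed: int = 0, start: int = 0
) -> np.ndarray:
    """Sample a state sequence from an exact transition matrix."""
    T = np.asarray(T, dtype=float)
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    states = np.empty(n_steps, dtype=np.int64)
    s = start
    u = rng.random(n_steps)
    for i in range(n_steps):
        states[i] = s
        s = int(np.searchsorted(cum[s], u[i]))
    return states


def markov_chain_ck_check(
    seed: int = 0, n_steps: int = 50_000, base_lag: float = 100.0
) -> dict:
    """Chapman–Kolmogorov and implied-timescale checks on an exact chain.

    A three-state metastable chain (exactly Markovian by construction) is
    sampled, an MSM is estimated at the chain's own time step, and the CK
    test is run for k ≤ 5; the predictions must fall inside the sampled 95%
    bands.  The implied-timescale closed form −τ/ln|λ₂| is returned for the
    two-state chain with λ₂ = 0.9 at τ = 100 ps (≈ 949.1 ps).
    """
    T_true = np.array(
        [
            [0.97, 0.02, 0.01],
            [0.03, 0.94, 0.03],
            [0.01, 0.04, 0.95],
        ]
    )
    states = sample_markov_chain(T_true, n_steps, seed=seed)
    dtraj = DiscreteTrajectory(
        states=states[:, None],
        times=np.arange(n_steps) * base_lag,
        stride=base_lag,
        molecule_ids=["chain"],
        n_states=3,
    )
    ck = chapman_kolmogorov(
        dtraj, base_lag=base_lag, steps=(1, 2, 3, 4, 5), n_sets=2,
        n_samples=200, seed=seed,
    )
    # two-state closed form: T = [[0.95, 0.05], [0.05, 0.95]] has λ₂ = 0.9
    two_state = DiscreteTrajectory(
        states=sample_markov_chain(
            np.array([[0.95, 0.05], [0.05, 0.95]]), 200_000, seed=seed + 1
        )[:, None],
        times=np.arange(200_000) * base_lag,
        stride=base_lag,
        molecule_ids=["chain"],
        n_states=2,
    )
    its = implied_timescales(two_state, lags=[base_lag, 2 * base_lag], k=1)
    model2 = estimate_msm(two_state, lag=base_lag)
    lam2 = float(np.sort(np.abs(np.real(model2.eigenvalues(1))))[0])
    # the same formula on the exactly-specified two-state matrix
    import scipy.sparse as sp

    from .grid_msm import MSMModel

    exact = MSMModel(
        active_states=np.array([0, 1]),
        transition_matrix=sp.csr_matrix(np.array([[0.95, 0.05], [0.05, 0.95]])),
        pi=np.array([0.5, 0.5]),
        lag=base_lag,
    )
    lam_exact = float(np.abs(exact.eigenvalues(1))[1])
    return {
        "its_exact_ps": -base_lag / np.log(lam_exact),
        "ck_passed": ck.passed,
        "ck_predicted": ck.predicted,
        "ck_lower": ck.ci_lower,
        "ck_upper": ck.ci_upper,
        "its_closed_form_ps": -base_lag / np.log(0.9),
        "its_estimated_ps": float(its.timescales[0, 0]),
        "lambda2_estimated": lam2,
        "n_steps": n_steps,
    }
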