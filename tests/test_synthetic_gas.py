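"""Brownian simulator, first-passage sampler and equilibrium oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from gasport.grid_msm import GridSpec
from gasport.synthetic_gas import (
    BrownianParams,
    SyntheticSystem,
    WellSpec,
    boltzmann_reference,
    brute_force_mfpt,
    scripted_fixture,
    shell_mfpt_analytic,
    simulate_brownian,
)


def test_free_diffusion_step_variance():
    """Per-dimension single-step displacement variance is 2·D·dt."""
    system = SyntheticSystem(box_half_edge=100.0)
    params = BrownianParams(n_molecules=100, n_steps=1000, dt=0.01,
                            save_stride=0.01, seed=0)
    traj = simulate_brownian(system, params)
    disp = np.diff(traj.positions, axis=0)
    var = disp.var()
    n = disp.size
    se = var * np.sqrt(2.0 / n)
    assert abs(var - 0.02) < 3 * se


def test_seed_determinism():
    system = SyntheticSystem(box_half_edge=20.0, wells=(WellSpec("w", (5, 0, 0), 3.0, 2.0),))
    params = BrownianParams(n_molecules=10, n_steps=500, dt=0.01, save_stride=0.1, seed=7)
    a = simulate_brownian(system, params)
    b = simulate_brownian(system, params)
    np.testing.assert_array_equal(a.positions, b.positions)


def test_reflecting_walls_contain_molecules():
    system = SyntheticSystem(box_half_edge=5.0, sink_radius=2.0)
    params = BrownianParams(n_molecules=50, n_steps=20_000, dt=0.05,
                            save_stride=0.05, seed=1)
    traj = simulate_brownian(system, params)
    assert np.abs(traj.positions).max() <= 5.0


def test_well_increases_occupancy():
    """A 4 kT well holds molecules longer than the same region without it."""
    well = WellSpec("w", (0.0, 0.0, 0.0), 4.0, 4.0)
    params = BrownianParams(n_molecules=100, n_steps=50_000, dt=0.01,
                            save_stride=1.0, seed=2)
    with_well = simulate_brownian(SyntheticSystem(10.0, (well,)), params)
    without = simulate_brownian(SyntheticSystem(10.0), params)
    frac_with = (with_well.distances < 4.0).mean()
    frac_without = (without.distances < 4.0).mean()
    assert frac_with > frac_without


def test_unstable_timestep_rejected():
    well = WellSpec("w", (0.0, 0.0, 0.0), 0.5, 50.0)
    with pytest.raises(ValueError, match="unstable"):
        simulate_brownian(
            SyntheticSystem(10.0, (well,)),
            BrownianParams(n_molecules=1, n_steps=10, dt=1.0, save_stride=1.0),
        )


def test_source_equals_sink_gives_zero():
    system = SyntheticSystem(box_half_edge=20.0, sink_radius=6.0)
    res = brute_force_mfpt(system, BrownianParams(n_molecules=1, n_steps=1, seed=0),
                           source_radius=6.0, sink_radius=6.0, n_events=100)
    assert res.mean == 0.0


def test_cavity_traps_slow_first_passage():
    """4 kT cavity traps between source and sink increase the MFPT.

    The traps sit on an octahedral ring at mid-radius so they intercept the
    inbound paths, like the hydrophobic-cavity shell of a buried active
    site.  (A single localized well adjacent to the absorber does *not*
    reliably slow passage: walkers bypass it, and trapped ones are released
    next to the sink, so capacitance enhancement cancels the retention —
    the trap must be separated from the sink and cover the path.)
    """
    centers = [(7.5, 0, 0), (-7.5, 0, 0), (0, 7.5, 0), (0, -7.5, 0), (0, 0, 7.5), (0, 0, -7.5)]
    wells = tuple(WellSpec(f"w{i}", c, 3.0, 4.0) for i, c in enumerate(centers))
    params = BrownianParams(n_molecules=1, n_steps=1, dt=0.04, seed=3)
    free = brute_force_mfpt(SyntheticSystem(13.0, sink_radius=2.0), params,
                            source_radius=11.0, n_events=3000)
    trapped = brute_force_mfpt(SyntheticSystem(13.0, wells, sink_radius=2.0), params,
                               source_radius=11.0, n_events=3000)
    # difference exceeds twice its standard error
    assert trapped.mean - free.mean > 2 * np.hypot(free.se, trapped.se)


def test_shell_mfpt_closed_form_value():
    # τ = (b³/3D)(1/a − 1/r0) − (r0²−a²)/6D ≈ 250.4 ps for a=6, b=r0=20, D=1
    assert shell_mfpt_analytic(1.0, 6.0, 20.0, 20.0) == pytest.approx(250.444, abs=0.001)


def test_boltzmann_uniform_and_normalized():
    system = SyntheticSystem(box_half_edge=10.0)
    grid = GridSpec(spacing=1.0, half_edge=8.0, wrap_mode="clamp")
    ids, w = boltzmann_reference(system, grid)
    assert w.sum() == pytest.approx(1.0)
    np.testing.assert_allclose(w, 1.0 / len(ids))  # zero potential → uniform


def test_boltzmann_well_occupancy_matches_quadrature():
    """Summed well occupancy against the continuous Boltzmann integral."""
    depth = np.log(2.0)
    wells = (
        WellSpec("flat", (-5.0, 0, 0), 3.0, 0.0),
        WellSpec("deep", (5.0, 0, 0), 3.0, depth),
    )
    system = SyntheticSystem(box_half_edge=10.0, wells=wells)
    grid = GridSpec(spacing=0.5, half_edge=10.0, wrap_mode="clamp")
    ids, w = boltzmann_reference(system, grid)
    coords = grid.state_coords(ids)
    in_deep = np.linalg.norm(coords - np.array([5.0, 0, 0]), axis=1) <= 3.0
    in_flat = np.linalg.norm(coords - np.array([-5.0, 0, 0]), axis=1) <= 3.0
    # ⟨e^{depth·S(u)}⟩ over the sphere with S the C¹ smoothstep profile
    boost, _ = quad(lambda u: 3 * u**2 * np.exp(depth * (1 - 3 * u**2 + 2 * u**3)), 0, 1)
    expected_ratio = boost
    ratio = w[in_deep].sum() / w[in_flat].sum()
    assert ratio == pytest.approx(expected_ratio, rel=0.02)


def test_scripted_fixture_validation():
    with pytest.raises(ValueError, match="duplicate"):
        scripted_fixture([(0.0, "m", (1, 0, 0)), (0.0, "m", (2, 0, 0))])
    with pytest.raises(ValueError, match="two frames"):
        scripted_fixture([(0.0, "m", (1, 0, 0))])


def test_scripted_fixture_hits_waypoints(dip_trajectory):
    assert dip_trajectory.positions[0, 0, 0] == 25.0
    assert dip_trajectory.positions[3, 0, 0] == pytest.approx(4.0)
    assert dip_trajectory.positions[-1, 0, 0] == 25.0
    assert dip_trajectory.stride == 10.0
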