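"""Synthetic flooded-gas trajectories with known kinetics.

The generator emulates what a flooded-gas MD simulation hands to the
analysis: many mutually non-interacting gas molecules diffusing around a
fixed catalytic center, with smooth attractive wells standing in for the
hydrophobic cavities that trap the gas, produce long-tailed residence times
and subdiffusive mean squared displacement.  Ground truth comes from closed
forms (spherical-shell first-passage time, Boltzmann weights) and from
brute-force first-passage sampling.

Dynamics are overdamped (position) Langevin, integrated by Euler–Maruyama:

    x ← x − D ∇U dt + sqrt(2 D dt) ξ,   ξ ~ N(0, 1) per dimension,

with reflecting walls at the box faces.  Units: Å, ps, kT = 1 by convention
(well depths are given in kT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_model import EnvironmentModel, RelativeTrajectory, Residue

__all__ = [
    "WellSpec",
    "SyntheticSystem",
    "BrownianParams",
    "FirstPassageResult",
    "simulate_brownian",
    "brute_force_mfpt",
    "boltzmann_reference",
    "scripted_fixture",
    "shell_mfpt_analytic",
]

# discrete-time absorbing-boundary shift constant (Mannella / Gobet):
# checking absorption only at multiples of dt behaves like a continuum
# boundary displaced inward by ~0.5826*sqrt(2 D dt).
BOUNDARY_SHIFT_CONST = 0.5826


@dataclass(frozen=True)
class WellSpec:
    """A smooth attractive spherical well (synthetic hydrophobic cavity).

    The potential is U(d) = −depth · S(d/radius) with the C¹ smoothstep
    S(u) = 1 − 3u² + 2u³ for u < 1 and 0 outside, so the force exists
    everywhere and vanishes at the rim and the center.
    """

    well_id: str
    center: tuple[float, float, float]
    radius: float
    depth: float  # kT, >= 0
    n_lining: int = 12  # pseudo-atoms placed on the well surface

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("well radius must be positive")
        if self.depth < 0:
            raise ValueError("well depth must be nonnegative")


@dataclass(frozen=True)
class SyntheticSystem:
    """Box + anchor + wells; the anchor (catalytic metal) sits at the origin."""

    box_half_edge: float
    wells: tuple[WellSpec, ...] = ()
    sink_radius: float = 6.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well ids must be unique")
        if self.sink_radius >= self.box_half_edge:
            raise ValueError("sink_radius must be smaller than box_half_edge")
        for w in self.wells:
            if np.max(np.abs(w.center)) > self.box_half_edge:
                raise ValueError(f"well {w.well_id} center outside the box")

    def potential(self, x: np.ndarray) -> np.ndarray:
        """U(x) in kT for positions (..., 3)."""
        x = np.asarray(x, dtype=float)
        U = np.zeros(x.shape[:-1])
        for w in self.wells:
            d = np.linalg.norm(x - np.asarray(w.center), axis=-1)
            u = np.clip(d / w.radius, 0.0, 1.0)
            U -= w.depth * (1.0 - 3.0 * u**2 + 2.0 * u**3)
        return U

    def grad_potential(self, x: np.ndarray) -> np.ndarray:
        """∇U(x) in kT/Å for positions (..., 3)."""
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for w in self.wells:
            rel = x - np.asarray(w.center)
            d = np.linalg.norm(rel, axis=-1)
            inside = (d < w.radius) & (d > 1e-12)
            u = d[inside] / w.radius
            # dU/dd = depth * 6 u (1-u) / radius, directed outward (attractive)
            mag = w.depth * 6.0 * u * (1.0 - u) / w.radius
            g[inside] += (mag / d[inside])[:, None] * rel[inside]
        return g

    def environment(self, seed: int = 0) -> EnvironmentModel:
        """Pseudo-residues on each well surface, labeled by well id.

        Lining atoms sit on a deterministic Fibonacci lattice over the well
        sphere, one single-atom residue each, so contact classification has
        unambiguous ground truth.  Regions map each well id to its lining.
        """
        residues: list[Residue] = []
        regions: dict[str, set[str]] = {}
        for w in self.wells:
            pts = _fibonacci_sphere(w.n_lining) * w.radius + np.asarray(w.center)
            ids = set()
            for i, p in enumerate(pts):
                rid = f"{w.well_id}_L{i:02d}"
                residues.append(Residue(rid, w.well_id, p[None, :]))
                ids.add(rid)
            regions[w.well_id] = ids
        return EnvironmentModel(residues, regions)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


@dataclass(frozen=True)
class BrownianParams:
    """Integration parameters; kT = 1 fixes the energy unit."""

    n_molecules: int = 100
    n_steps: int = 10_000
    diffusion_coefficient: float = 1.0  # Å²/ps
    dt: float = 0.01  # ps
    save_stride: float = 1.0  # ps
    seed: int = 0
    kT: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.diffusion_coefficient <= 0:
            raise ValueError("dt and D must be positive")
        k = self.save_stride / self.dt
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError("save_stride must be a positive integer multiple of dt")

    @property
    def save_every(self) -> int:
        return int(round(self.save_stride / self.dt))


def _check_stability(system: SyntheticSystem, params: BrownianParams) -> None:
    D, dt = params.diffusion_coefficient, params.dt
    for w in system.wells:
        # max |∇U| of the smoothstep well is 1.5 depth / radius (at u = 1/2)
        max_drift = D * 1.5 * w.depth / w.radius * dt
        if max_drift > w.radius / 2:
            raise ValueError(
                f"dt={dt} ps unstable for well {w.well_id}: drift per step "
                f"{max_drift:.3g} Å exceeds radius/2"
            )


def _reflect_box(x: np.ndarray, L: float) -> None:
    """Reflect positions into [−L, L] in place (single bounce per step)."""
    np.copyto(x, np.where(x > L, 2 * L - x, x))
    np.copyto(x, np.where(x < -L, -2 * L - x, x))
    np.clip(x, -L, L, out=x)  # guard against pathological multi-crossings


def simulate_brownian(
    system: SyntheticSystem,
    params: BrownianParams,
    start: np.ndarray | None = None,
) -> RelativeTrajectory:
    """Simulate non-interacting gas molecules; returns an anchor-relative trajectory.

    Positions start uniform in the box unless ``start`` (n_molecules, 3) is
    given.  Output frames are saved every ``save_stride`` ps, including t=0.
    Identical seeds give identical trajectories.
    """
    _check_stability(system, params)
    rng = np.random.default_rng(params.seed)
    L = system.box_half_edge
    n = params.n_molecules
    if start is None:
        x = rng.uniform(-L, L, size=(n, 3))
    else:
        x = np.array(start, dtype=float)
        if x.shape != (n, 3):
            raise ValueError("start must have shape (n_molecules, 3)")
    D, dt = params.diffusion_coefficient, params.dt
    noise_scale = np.sqrt(2 * D * dt)
    n_saved = params.n_steps // params.save_every + 1
    out = np.empty((n_saved, n, 3))
    out[0] = x
    si = 1
    has_wells = len(system.wells) > 0
    for step in range(1, params.n_steps + 1):
        if has_wells:
            x += -D * system.grad_potential(x) * dt
        x += noise_scale * rng.standard_normal((n, 3))
        _reflect_box(x, L)
        if step % params.save_every == 0:
            out[si] = x
            si += 1
    times = np.arange(n_saved) * params.save_stride
    mol_ids = [f"O2_{i:04d}" for i in range(n)]
    return RelativeTrajectory(
        times=times,
        molecule_ids=mol_ids,
        positions=out[:si],
        stride=params.save_stride,
        superposed=True,
        source=f"synthetic(seed={params.seed})",
    )


@dataclass
class FirstPassageResult:
    """Sampled first-passage statistics (times in ps)."""

    mean: float
    se: float
    times: np.ndarray
    n_censored: int = 0


def shell_mfpt_analytic(
    D: float, a: float, b: float, r0: float
) -> float:
    """Closed-form MFPT (ps) for free diffusion in a spherical shell.

    Absorbing sphere at radius ``a``, reflecting sphere at ``b``, start at
    radius ``r0``:  τ = (b³/3D)(1/a − 1/r0) − (r0² − a²)/6D.
    """
    return (b**3 / (3 * D)) * (1 / a - 1 / r0) - (r0**2 - a**2) / (6 * D)


def brute_force_mfpt(
    system: SyntheticSystem,
    params: BrownianParams,
    source_radius: float,
    sink_radius: float | None = None,
    n_events: int = 10_000,
    max_steps: int | None = None,
    outer_boundary: str = "box",
    boundary_correction: bool = True,
    absorb_interval: float | None = None,
) -> FirstPassageResult:
    """Mean first-passage time from the source shell to the sink by sampling.

    ``n_events`` independent walkers start uniformly distributed on the
    sphere of radius ``source_radius`` and are absorbed when their distance
    to the anchor first drops below the sink radius (default: the system's
    sink).  The outer boundary reflects either at the box faces (``"box"``,
    matching :func:`simulate_brownian`) or radially at a sphere of radius
    ``box_half_edge`` (``"sphere"``, matching the closed-form shell MFPT).

    ``boundary_correction`` applies the standard discrete-time shift to the
    absorbing radius (+0.5826·sqrt(2 D dt)) so the sampled mean converges to
    the continuum first-passage time.  Reflecting boundaries need no shift:
    specular folding applied every step reproduces reflected Brownian motion
    in law, only discrete-time *absorption* misses sub-step crossings.

    ``absorb_interval`` (ps) checks absorption only at multiples of that
    interval instead of every step.  This is the matching oracle for an MSM
    at lag τ: a lag-τ model observes first passage at time resolution τ, so
    its MFPT must be compared against first-passage samples observed the
    same way.  Boundary corrections are disabled in this mode — the walkers
    then follow exactly the dynamics of :func:`simulate_brownian` sampled at
    the interval.
    """
    sink = system.sink_radius if sink_radius is None else sink_radius
    if not sink <= source_radius <= system.box_half_edge + 1e-9:
        raise ValueError("need sink_radius <= source_radius <= box_half_edge")
    _check_stability(system, params)
    rng = np.random.default_rng(params.seed)
    D, dt = params.diffusion_coefficient, params.dt
    noise_scale = np.sqrt(2 * D * dt)
    check_every = 1
    if absorb_interval is not None:
        k = absorb_interval / dt
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError("absorb_interval must be a positive integer multiple of dt")
        check_every = int(round(k))
        boundary_correction = False
    shift = BOUNDARY_SHIFT_CONST * noise_scale if boundary_correction else 0.0
    sink_eff = sink + shift
    L = system.box_half_edge
    sphere_R = L if outer_boundary == "sphere" else None
    if max_steps is None:
        max_steps = int(5e7 // max(n_events, 1)) * 100 + 1_000_000

    # start uniformly on the source sphere
    u = rng.standard_normal((n_events, 3))
    x = u / np.linalg.norm(u, axis=1, keepdims=True) * source_radius
    times = np.full(n_events, np.nan)
    alive = np.arange(n_events)
    if sink >= source_radius:  # already inside the sink shell
        return FirstPassageResult(0.0, 0.0, np.zeros(n_events))
    has_wells = len(system.wells) > 0
    step = 0
    while len(alive) and step < max_steps:
        step += 1
        if has_wells:
            x += -D * system.grad_potential(x) * dt
        x += noise_scale * rng.standard_normal(x.shape)
        if outer_boundary == "sphere":
            r = np.linalg.norm(x, axis=1)
            out = r > sphere_R
            if np.any(out):
                x[out] *= ((2 * sphere_R - r[out]) / r[out])[:, None]
        else:
            _reflect_box(x, L)
        if step % check_every:
            continue
        r = np.linalg.norm(x, axis=1)
        hit = r < sink_eff
        if np.any(hit):
            times[alive[hit]] = step * dt
            keep = ~hit
            alive = alive[keep]
            x = x[keep]
    n_censored = len(alive)
    if n_censored:
        warnings.warn(
            f"{n_censored} of {n_events} walkers not absorbed within {max_steps} steps"
        )
    done = times[np.isfinite(times)]
    if len(done) == 0:
        raise RuntimeError("no first-passage events observed")
    mean = float(done.mean())
    se = float(done.std(ddof=1) / np.sqrt(len(done))) if len(done) > 1 else 0.0
    return FirstPassageResult(mean, se, done, n_censored)


def boltzmann_reference(system: SyntheticSystem, grid) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium weights ∝ exp(−U/kT) at the in-box grid points.

    Each state is weighted by the Boltzmann factor at its grid point times
    the fraction of its grid cell that lies inside the box (cells straddling
    a box face only collect samples from their in-box part).  Returns
    ``(state_ids, weights)`` with weights normalized to 1 over the in-box
    states — the analytic oracle for the MSM stationary distribution of an
    equilibrium run.
    """
    all_states = np.arange(grid.n_states, dtype=np.int64)
    coords = grid.state_coords(all_states)
    L = system.box_half_edge
    half = grid.spacing / 2.0
    lo = np.maximum(coords - half, -L)
    hi = np.minimum(coords + half, L)
    overlap = np.clip(hi - lo, 0.0, None)
    volume = np.prod(overlap, axis=1) / grid.spacing**3
    inside = volume > 1e-12
    ids = all_states[inside]
    w = np.exp(-system.potential(coords[inside]) / 1.0) * volume[inside]
    return ids, w / w.sum()


def scripted_fixture(
    waypoints: list[tuple[float, str, tuple[float, float, float]]],
    save_stride: float = 10.0,
) -> RelativeTrajectory:
    """Hand-checkable trajectory passing exactly through given waypoints.

    ``waypoints`` are ``(time_ps, molecule_id, position)``; each molecule's
    path is linearly interpolated on the common time grid at ``save_stride``
    and held constant before its first / after its last waypoint.
    """
    if not waypoints:
        raise ValueError("need at least one waypoint")
    seen = set()
    per_mol: dict[str, list[tuple[float, np.ndarray]]] = {}
    for t, mid, pos in waypoints:
        if (t, mid) in seen:
            raise ValueError(f"duplicate waypoint (t={t}, molecule={mid!r})")
        seen.add((t, mid))
        per_mol.setdefault(mid, []).append((float(t), np.asarray(pos, dtype=float)))
    for mid, pts in per_mol.items():
        times = [t for t, _ in pts]
        if times != sorted(times):
            raise ValueError(f"waypoints for molecule {mid!r} are not time-ordered")
    t0 = min(t for t, _, _ in waypoints)
    t1 = max(t for t, _, _ in waypoints)
    n_frames = int(round((t1 - t0) / save_stride)) + 1
    if n_frames < 2:
        raise ValueError("waypoints must span at least two frames")
    times = t0 + np.arange(n_frames) * save_stride
    mol_ids = sorted(per_mol)
    positions = np.empty((n_frames, len(mol_ids), 3))
    for mi, mid in enumerate(mol_ids):
        pts = per_mol[mid]
        wt = np.array([t for t, _ in pts])
        wp = np.vstack([p for _, p in pts])
        for dim in range(3):
            positions[:, mi, dim] = np.interp(times, wt, wp[:, dim])
    return RelativeTrajectory(
        times=times,
        molecule_ids=mol_ids,
        positions=positions,
        stride=save_stride,
        superposed=True,
        source="scripted_fixture",
    )
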