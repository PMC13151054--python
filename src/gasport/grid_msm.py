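"""Grid-discretized Markov state models of gas positions.

Anchor-relative gas positions are rounded to the nearest point of a cubic
grid (default 1 Å spacing, 40 Å cube centered on the catalytic metal, i.e. a
theoretical maximum of 40³ = 64,000 states).  Positions outside the cube are
either wrapped by minimum image with the cube period (``periodic``, the
default) or clamped to the nearest face (``clamp``).

From the integer state sequences the module builds sliding-window transition
count matrices at a lag time τ, the maximum-likelihood transition matrix
(per-row normalization of the counts, which maximizes ∏ T_ij^c_ij), the
stationary distribution on the largest strongly connected component, implied
timescales, Chapman–Kolmogorov validation, Bayesian (Dirichlet) posterior
samples, and milestoning-reduced core-set models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

NULL_STATE = -1

__all__ = [
    "GridSpec",
    "DiscreteTrajectory",
    "CountMatrix",
    "MSMModel",
    "ImpliedTimescales",
    "CKReport",
    "assign_states",
    "restrict_to_events",
    "count_transitions",
    "estimate_msm",
    "validate_msm",
    "sample_bayesian",
    "reduce_milestoning",
    "select_source_sink",
    "stationary_distribution",
]


@dataclass(frozen=True)
class GridSpec:
    """Cubic state-space grid centered on the anchor.

    Grid points sit at integer multiples of ``spacing`` in each dimension.
    Under ``periodic`` wrapping the +half_edge and −half_edge faces are
    identified (minimum image with period ``2*half_edge``), giving
    ``(2*half_edge/spacing)**3`` distinct states; under ``clamp`` both faces
    are distinct states.
    """

    spacing: float = 1.0
    half_edge: float = 20.0
    wrap_mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.half_edge <= 0:
            raise ValueError("grid half_edge must be positive")
        if self.wrap_mode not in ("periodic", "clamp"):
            raise ValueError("wrap_mode must be 'periodic' or 'clamp'")
        n = 2 * self.half_edge / self.spacing
        if abs(n - round(n)) > 1e-9:
            raise ValueError("2*half_edge must be an integer multiple of spacing")

    @property
    def half_n(self) -> int:
        return int(round(self.half_edge / self.spacing))

    @property
    def n_per_axis(self) -> int:
        n = int(round(2 * self.half_edge / self.spacing))
        return n if self.wrap_mode == "periodic" else n + 1

    @property
    def n_states(self) -> int:
        """Theoretical state-space capacity (occupied or not)."""
        return self.n_per_axis**3

    def assign(self, positions: np.ndarray) -> np.ndarray:
        """Map positions (..., 3) in Å to linear state ids."""
        g = np.rint(np.asarray(positions, dtype=float) / self.spacing).astype(np.int64)
        n = self.n_per_axis
        if self.wrap_mode == "periodic":
            idx = np.mod(g + self.half_n, n)  # -half_n .. half_n-1 -> 0 .. n-1
        else:
            idx = np.clip(g, -self.half_n, self.half_n) + self.half_n
        return (idx[..., 0] * n + idx[..., 1]) * n + idx[..., 2]

    def state_coords(self, states: np.ndarray) -> np.ndarray:
        """Inverse mapping: linear state ids to grid-point coordinates (Å)."""
        states = np.asarray(states, dtype=np.int64)
        n = self.n_per_axis
        iz = states % n
        iy = (states // n) % n
        ix = states // (n * n)
        return np.stack([ix, iy, iz], axis=-1) * self.spacing - self.half_edge

    def state_distances(self, states: np.ndarray) -> np.ndarray:
        """Distance from each state's grid point to the anchor (Å)."""
        return np.linalg.norm(self.state_coords(states), axis=-1)


@dataclass
class DiscreteTrajectory:
    """Integer state sequences at a fixed stride; ``-1`` marks null frames."""

    states: np.ndarray  # (n_frames, n_molecules)
    times: np.ndarray  # ps
    stride: float  # ps
    molecule_ids: list[str]
    grid: GridSpec | None = None
    n_states: int | None = None  # capacity; defaults to grid capacity

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=np.int64))
        self.times = np.asarray(self.times, dtype=float)
        if self.n_states is None:
            if self.grid is None:
                raise ValueError("either grid or n_states must be given")
            self.n_states = self.grid.n_states
        if self.states.size and (self.states.max() >= self.n_states or self.states.min() < -1):
            raise ValueError("state ids out of range")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.states.shape[1]

    def visited_states(self) -> np.ndarray:
        s = np.unique(self.states)
        return s[s != NULL_STATE]


@dataclass
class CountMatrix:
    """Sliding-window transition counts at a lag time."""

    counts: sp.csr_matrix
    lag: float  # ps
    stride: float  # ps
    sliding: bool = True

    @property
    def lag_frames(self) -> int:
        return int(round(self.lag / self.stride))


@dataclass
class MSMModel:
    """A Markov state model on its active set of grid states."""

    active_states: np.ndarray  # global state ids, sorted
    transition_matrix: sp.csr_matrix  # row-stochastic, active × active
    pi: np.ndarray  # stationary distribution over active states
    lag: float  # ps
    counts: CountMatrix | None = None
    grid: GridSpec | None = None
    estimator: str = "MLE"

    def __post_init__(self) -> None:
        rows = np.asarray(self.transition_matrix.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_active(self) -> int:
        return len(self.active_states)

    def local_index(self, global_states) -> np.ndarray:
        """Map global state ids to indices into the active set (-1 if absent)."""
        global_states = np.atleast_1d(np.asarray(global_states, dtype=np.int64))
        pos = np.searchsorted(self.active_states, global_states)
        pos = np.clip(pos, 0, self.n_active - 1)
        ok = self.active_states[pos] == global_states
        return np.where(ok, pos, -1)

    def eigenvalues(self, k: int = 5) -> np.ndarray:
        """Leading eigenvalues of T, sorted by decreasing magnitude."""
        n = self.n_active
        if n <= max(k + 2, 50):
            vals = np.linalg.eigvals(self.transition_matrix.toarray())
        else:
            vals = spla.eigs(self.transition_matrix.astype(float), k=min(k + 1, n - 2),
                             which="LM", return_eigenvectors=False)
        order = np.argsort(-np.abs(vals))
        return vals[order][: k + 1]


def assign_states(
    traj, grid: GridSpec, stride: float | None = None
) -> DiscreteTrajectory:
    """Discretize an anchor-relative trajectory onto the grid.

    If ``stride`` (ps) is coarser than the trajectory stride, the trajectory
    is decimated first (it must be an integer multiple).
    """
    if stride is not None and stride != traj.stride:
        factor = stride / traj.stride
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError("MSM stride must be an integer multiple of the trajectory stride")
        traj = traj.decimate(int(round(factor)))
    states = grid.assign(traj.positions)
    return DiscreteTrajectory(
        states=states,
        times=traj.times,
        stride=traj.stride,
        molecule_ids=list(traj.molecule_ids),
        grid=grid,
    )


def restrict_to_events(dtraj: DiscreteTrajectory, events) -> DiscreteTrajectory:
    """Null out every frame not inside a traced event span.

    Events carry per-molecule time spans (outer shell to outer shell); frames
    outside the union of the spans of their molecule become null states.
    """
    keep = np.zeros_like(dtraj.states, dtype=bool)
    mol_index = {m: i for i, m in enumerate(dtraj.molecule_ids)}
    for ev in events:
        mi = mol_index.get(ev.molecule_id)
        if mi is None:
            continue
        t0, t1 = ev.span_times
        keep[:, mi] |= (dtraj.times >= t0) & (dtraj.times <= t1)
    states = np.where(keep, dtraj.states, NULL_STATE)
    return DiscreteTrajectory(
        states=states,
        times=dtraj.times,
        stride=dtraj.stride,
        molecule_ids=list(dtraj.molecule_ids),
        grid=dtraj.grid,
        n_states=dtraj.n_states,
    )


def count_transitions(dtraj: DiscreteTrajectory, lag: float) -> CountMatrix:
    """Sliding-window transition counts at lag τ (pairs with nulls dropped)."""
    k = lag / dtraj.stride
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError("lag must be a positive integer multiple of the stride")
    k = int(round(k))
    if k >= dtraj.n_frames:
        raise ValueError("lag exceeds trajectory length")
    src = dtraj.states[:-k].ravel(order="F")
    dst = dtraj.states[k:].ravel(order="F")
    ok = (src != NULL_STATE) & (dst != NULL_STATE)
    n = dtraj.n_states
    counts = sp.coo_matrix(
        (np.ones(ok.sum()), (src[ok], dst[ok])), shape=(n, n)
    ).tocsr()
    return CountMatrix(counts=counts, lag=lag, stride=dtraj.stride)


def _active_set(counts: sp.csr_matrix) -> np.ndarray:
    """States kept in the model: the largest strongly connected count set.

    Unvisited states and states with no observed transitions are excluded;
    among the rest the largest strongly connected component of the directed
    count graph is retained, so every kept row has outgoing counts within
    the kept set (dangling segment ends would otherwise cascade rows to
    zero under plain row trimming).
    """
    rows = np.asarray(counts.sum(axis=1)).ravel()
    cols = np.asarray(counts.sum(axis=0)).ravel()
    visited = (rows + cols) > 0
    if not visited.any():
        raise ValueError("no states with observed transitions")
    ncomp, labels = connected_components(counts, directed=True, connection="strong")
    sizes = np.bincount(labels[visited], minlength=ncomp)
    active = np.flatnonzero((labels == sizes.argmax()) & visited)
    if len(active) == 1:
        if counts[active[0], active[0]] <= 0:
            raise ValueError("count graph has no connected transitions")
    return active


def stationary_distribution(T: sp.csr_matrix) -> np.ndarray:
    """Stationary distribution: leading left eigenvector on the largest SCC.

    States outside the largest strongly connected component get zero weight;
    the result is renormalized to sum to 1.
    """
    n = T.shape[0]
    ncomp, labels = connected_components(T, directed=True, connection="strong")
    if ncomp > 1:
        largest = np.bincount(labels).argmax()
        idx = np.flatnonzero(labels == largest)
    else:
        idx = np.arange(n)
    Tsub = T[np.ix_(idx, idx)].toarray() if len(idx) <= 800 else T[np.ix_(idx, idx)]
    if sp.issparse(Tsub):
        # power iteration is robust for large sparse substochastic-free blocks
        vals, vecs = spla.eigs(Tsub.T.astype(float), k=1, which="LM")
        v = np.real(vecs[:, 0])
    else:
        vals, vecs = np.linalg.eig(np.asarray(Tsub).T)
        v = np.real(vecs[:, np.argmax(np.real(vals))])
    v = np.abs(v)
    pi = np.zeros(n)
    pi[idx] = v / v.sum()
    return pi


def estimate_msm(
    dtraj: DiscreteTrajectory, lag: float, counts: CountMatrix | None = None
) -> MSMModel:
    """Maximum-likelihood MSM at lag τ.

    The likelihood L(T) = ∏ T_ij^c_ij is maximized row-wise by
    T̂_ij = c_ij / Σ_k c_ik on the active set.
    """
    if counts is None:
        counts = count_transitions(dtraj, lag)
    if counts.counts.nnz == 0:
        raise ValueError("empty count matrix: no observed transitions")
    active = _active_set(counts.counts)
    C = counts.counts[np.ix_(active, active)].astype(float)
    rowsum = np.asarray(C.sum(axis=1)).ravel()
    T = sp.diags(1.0 / rowsum) @ C
    pi = stationary_distribution(T.tocsr())
    return MSMModel(
        active_states=active,
        transition_matrix=T.tocsr(),
        pi=pi,
        lag=lag,
        counts=counts,
        grid=dtraj.grid,
    )


# ---------------------------------------------------------------------------
# validation: implied timescales and Chapman–Kolmogorov


@dataclass
class ImpliedTimescales:
    """Implied timescales t_k(τ) = −τ / ln|λ_k(τ)| across a lag scan."""

    lags: np.ndarray  # ps
    timescales: np.ndarray  # (n_lags, k); inf marks divergent (λ ≈ 1)
    eigenvalues: np.ndarray  # (n_lags, k) magnitudes of nontrivial λ


@dataclass
class CKReport:
    """Chapman–Kolmogorov comparison of T(τ)^k against models at kτ."""

    base_lag: float
    steps: np.ndarray  # multiples k
    sets: list[np.ndarray]  # metastable sets, local indices of the base model
    predicted: np.ndarray  # (n_steps, n_sets) set self-transition probability
    estimated: np.ndarray  # (n_steps, n_sets) from the model at kτ
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    @property
    def passed(self) -> bool:
        """All predictions inside the sampled confidence band."""
        return bool(
            np.all((self.predicted >= self.ci_lower) & (self.predicted <= self.ci_upper))
        )


def implied_timescales(
    dtraj: DiscreteTrajectory, lags, k: int = 3, complex_tol: float = 1e-8
) -> ImpliedTimescales:
    lags = np.asarray(sorted(lags), dtype=float)
    if len(lags) < 2:
        raise ValueError("need at least 2 lag times")
    its = np.full((len(lags), k), np.nan)
    mags = np.full((len(lags), k), np.nan)
    for li, lag in enumerate(lags):
        model = estimate_msm(dtraj, lag)
        vals = model.eigenvalues(k)
        nontrivial = vals[1:]  # drop the stationary eigenvalue 1
        if np.any(np.abs(np.imag(nontrivial)) > complex_tol + 1e-6 * np.abs(nontrivial)):
            warnings.warn(f"complex eigenvalues at lag {lag} ps; timescales use |λ|")
        lam = np.abs(nontrivial)[:k]
        with np.errstate(divide="ignore"):
            t = -lag / np.log(lam)
        t[lam >= 1.0 - 1e-12] = np.inf  # divergent / identity-like mode
        its[li, : len(t)] = t
        mags[li, : len(lam)] = lam
    return ImpliedTimescales(lags=lags, timescales=its, eigenvalues=mags)


def _metastable_sets(model: MSMModel, n_sets: int, seed: int = 0) -> list[np.ndarray]:
    """Crude metastable partition: k-means on the leading right eigenvectors."""
    if n_sets < 2:
        raise ValueError("need at least 2 sets")
    n = model.n_active
    Td = model.transition_matrix.toarray() if n <= 2000 else None
    if Td is not None:
        vals, vecs = np.linalg.eig(Td)
        order = np.argsort(-np.abs(vals))
        comps = np.real(vecs[:, order[1:n_sets]])
    else:
        vals, vecs = spla.eigs(model.transition_matrix.astype(float), k=n_sets, which="LM")
        order = np.argsort(-np.abs(vals))
        comps = np.real(vecs[:, order[1:n_sets]])
    if n_sets == 2:
        labels = (comps[:, 0] >= np.median(comps[:, 0])).astype(int)
    else:
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=n_sets, n_init=10, random_state=seed).fit_predict(comps)
    return [np.flatnonzero(labels == s) for s in range(n_sets)]


def chapman_kolmogorov(
    dtraj: DiscreteTrajectory,
    base_lag: float,
    steps=(1, 2, 3, 4, 5),
    n_sets: int = 2,
    sets: list[np.ndarray] | None = None,
    n_samples: int = 100,
    seed: int = 0,
    ci: float = 0.95,
) -> CKReport:
    """CK test: compare T(τ)^k with models estimated directly at kτ.

    For each metastable set A the self-transition probability
    P(A→A; kτ) = Σ_{i∈A} w_i [T^k]_{iA} with w = π restricted to A is
    compared against the same quantity from the model estimated at kτ, with
    a confidence band from Bayesian posterior samples of that model.
    """
    model = estimate_msm(dtraj, base_lag)
    if sets is None:
        sets = _metastable_sets(model, n_sets, seed=seed)
    sets = [np.asarray(s, dtype=int) for s in sets]
    steps = np.asarray(sorted(steps), dtype=int)
    alpha = (1.0 - ci) / 2

    predicted = np.full((len(steps), len(sets)), np.nan)
    estimated = np.full_like(predicted, np.nan)
    lo = np.full_like(predicted, np.nan)
    hi = np.full_like(predicted, np.nan)

    Tk = sp.identity(model.n_active, format="csr")
    T = model.transition_matrix
    global_sets = [model.active_states[s] for s in sets]
    step_ptr = 0
    for k in range(1, steps.max() + 1):
        Tk = (Tk @ T).tocsr()
        if step_ptr >= len(steps) or k != steps[step_ptr]:
            continue
        model_k = estimate_msm(dtraj, base_lag * k)
        samples = sample_bayesian(model_k.counts, n_samples=n_samples, seed=seed + k)
        for si, (s_local, s_global) in enumerate(zip(sets, global_sets)):
            w = model.pi[s_local]
            if w.sum() == 0:
                continue
            w = w / w.sum()
            predicted[step_ptr, si] = float(w @ np.asarray(Tk[np.ix_(s_local, s_local)].sum(axis=1)).ravel())
            sk_local = model_k.local_index(s_global)
            sk_local = sk_local[sk_local >= 0]
            wk = model_k.pi[sk_local]
            wk = wk / wk.sum() if wk.sum() > 0 else np.full(len(sk_local), 1 / max(len(sk_local), 1))
            Tksub = model_k.transition_matrix[np.ix_(sk_local, sk_local)]
            estimated[step_ptr, si] = float(wk @ np.asarray(Tksub.sum(axis=1)).ravel())
            vals = []
            for smpl in samples:
                sl = smpl.local_index(s_global)
                sl = sl[sl >= 0]
                sub = smpl.transition_matrix[np.ix_(sl, sl)]
                ws = smpl.pi[sl]
                ws = ws / ws.sum() if ws.sum() > 0 else np.full(len(sl), 1 / max(len(sl), 1))
                vals.append(float(ws @ np.asarray(sub.sum(axis=1)).ravel()))
            lo[step_ptr, si] = np.quantile(vals, alpha)
            hi[step_ptr, si] = np.quantile(vals, 1 - alpha)
        step_ptr += 1
    return CKReport(
        base_lag=base_lag,
        steps=steps,
        sets=sets,
        predicted=predicted,
        estimated=estimated,
        ci_lower=lo,
        ci_upper=hi,
    )


def validate_msm(
    dtraj: DiscreteTrajectory,
    lags,
    n_sets: int = 2,
    ck_steps=(1, 2, 3, 4, 5),
    n_samples: int = 100,
    seed: int = 0,
) -> tuple[ImpliedTimescales, CKReport]:
    """Implied-timescale scan plus a Chapman–Kolmogorov test at the smallest lag."""
    its = implied_timescales(dtraj, lags)
    ck = chapman_kolmogorov(
        dtraj, base_lag=min(lags), steps=ck_steps, n_sets=n_sets,
        n_samples=n_samples, seed=seed,
    )
    return its, ck


# ---------------------------------------------------------------------------
# Bayesian posterior sampling


def sample_bayesian(
    counts: CountMatrix, n_samples: int = 100, seed: int = 0,
    prior_weight: float | None = None,
) -> list[MSMModel]:
    """Sample transition matrices from the per-row Dirichlet posterior.

    With observed counts c_i· and a uniform Dirichlet prior with pseudo-count
    ``prior_weight`` per state (default 1/N over the N active states), each
    row of T is drawn independently from Dirichlet(c_i + prior).
    """
    if counts is None or counts.counts.nnz == 0:
        raise ValueError("empty count matrix")
    active = _active_set(counts.counts)
    C = counts.counts[np.ix_(active, active)].toarray().astype(float)
    n = len(active)
    w = (1.0 / n) if prior_weight is None else prior_weight
    alpha = C + w
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_samples):
        T = np.vstack([rng.dirichlet(a) for a in alpha])
        T = T / T.sum(axis=1, keepdims=True)
        pi = stationary_distribution(sp.csr_matrix(T))
        out.append(
            MSMModel(
                active_states=active,
                transition_matrix=sp.csr_matrix(T),
                pi=pi,
                lag=counts.lag,
                counts=counts,
                estimator="Bayesian-sample",
            )
        )
    return out


# ---------------------------------------------------------------------------
# milestoning reduction and source/sink selection


def reduce_milestoning(
    dtraj: DiscreteTrajectory, core_sets: list
) -> DiscreteTrajectory:
    """Relabel every frame with the most recently visited core set.

    Frames before any core visit stay null.  The output trajectory has one
    state per core (0..n_cores-1).
    """
    cores = [np.asarray(sorted(c), dtype=np.int64) for c in core_sets]
    for i in range(len(cores)):
        for j in range(i + 1, len(cores)):
            if np.intersect1d(cores[i], cores[j]).size:
                raise ValueError(f"core sets {i} and {j} overlap")
    core_of = {}
    for ci, c in enumerate(cores):
        for s in c:
            core_of[int(s)] = ci
    out = np.full_like(dtraj.states, NULL_STATE)
    for mi in range(dtraj.n_molecules):
        last = NULL_STATE
        col = dtraj.states[:, mi]
        for fi in range(dtraj.n_frames):
            s = col[fi]
            if s != NULL_STATE and int(s) in core_of:
                last = core_of[int(s)]
            out[fi, mi] = last
    return DiscreteTrajectory(
        states=out,
        times=dtraj.times,
        stride=dtraj.stride,
        molecule_ids=list(dtraj.molecule_ids),
        grid=None,
        n_states=len(cores),
    )


def core_sets_by_distance(dtraj: DiscreteTrajectory, radii=(7.0,)) -> list[np.ndarray]:
    """Default cores: visited states binned by distance shells around the anchor.

    ``radii=(7.0,)`` gives two cores: event states within 7 Å of the metal,
    and everything beyond.
    """
    if dtraj.grid is None:
        raise ValueError("distance-based cores need a grid")
    visited = dtraj.visited_states()
    d = dtraj.grid.state_distances(visited)
    edges = [0.0, *sorted(radii), np.inf]
    return [
        visited[(d >= lo) & (d < hi)]
        for lo, hi in zip(edges[:-1], edges[1:])
    ]


def select_source_sink(
    dtraj: DiscreteTrajectory,
    events,
    r_sink: float = 6.7,
    r_source: float = 22.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Source and sink state sets for transition-path kinetics.

    Sink: every visited state whose grid point lies within ``r_sink`` Å of
    the metal.  Source: the specific states occupied at the event boundary
    frames — for entries the first frame after the molecule was beyond
    ``r_source``, for exits the last frame before it got there.
    """
    if dtraj.grid is None:
        raise ValueError("source/sink selection needs a grid")
    visited = dtraj.visited_states()
    dist = dtraj.grid.state_distances(visited)
    sink = visited[dist < r_sink]
    mol_index = {m: i for i, m in enumerate(dtraj.molecule_ids)}
    source: set[int] = set()
    for ev in events:
        if ev.censored:
            continue
        mi = mol_index.get(ev.molecule_id)
        if mi is None:
            continue
        fi = int(np.argmin(np.abs(dtraj.times - ev.t_outer)))
        # first in-range frame moving inward from the boundary
        step = 1 if ev.direction == "entry" else -1
        j = fi
        while 0 <= j < dtraj.n_frames:
            s = dtraj.states[j, mi]
            if s != NULL_STATE and dtraj.grid.state_distances(np.array([s]))[0] <= r_source:
                source.add(int(s))
                break
            j += step
    source_arr = np.array(sorted(source - set(sink.tolist())), dtype=np.int64)
    if len(sink) == 0 or len(source_arr) == 0:
        raise ValueError("empty source or sink set; check radii and events")
    return source_arr, sink
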