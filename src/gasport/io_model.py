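"""Core data types and I/O for gas-transport analysis.

The analysis works in *anchor-relative* coordinates: every gas position is
expressed relative to the catalytic metal center ("anchor") after an optional
rigid-body superposition of each frame onto a reference frame.  The sign
convention is ``gas - anchor`` (not ``anchor - gas``), so exported state
clouds overlay the protein frame naturally; distances are unaffected by the
choice.

Two plain-text trajectory formats are supported natively:

* the self-describing *columnar* format (header lines starting with ``#``
  carrying the stride and molecule ids; data rows ``time id x y z``, with the
  reserved ids ``ANCHOR`` and ``REF<k>`` for the catalytic center and the
  superposition reference atoms), and
* standard XYZ (element symbols; the anchor is the atom named ``Fe``, gas
  molecules are all other atoms, identified by their order within a frame).

Binary MD formats are an extension point: anything that can produce a
sequence of :class:`Frame` objects plugs into the same pipeline.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "RelativeTrajectory",
    "Residue",
    "EnvironmentModel",
    "StateCloud",
    "TrajectoryParseError",
    "SuperpositionError",
    "load_trajectory",
    "write_trajectory",
    "write_xyz",
    "superpose_and_center",
    "read_environment_pdb",
    "export_state_cloud",
    "classify_pi",
]

ANCHOR_ID = "ANCHOR"
REF_PREFIX = "REF"


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file is malformed."""


class SuperpositionError(ValueError):
    """Raised when a rigid-body fit cannot be computed."""


@dataclass
class Frame:
    """One time point: gas positions, anchor position, optional fit atoms.

    All coordinates are in Å, times in ps.
    """

    time: float
    gas_positions: dict[str, np.ndarray]
    anchor_position: np.ndarray
    reference_atoms: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.anchor_position = np.asarray(self.anchor_position, dtype=float)
        self.gas_positions = {
            k: np.asarray(v, dtype=float) for k, v in self.gas_positions.items()
        }
        if self.reference_atoms is not None:
            self.reference_atoms = np.asarray(self.reference_atoms, dtype=float)
        coords = list(self.gas_positions.values()) + [self.anchor_position]
        if not all(np.all(np.isfinite(c)) for c in coords):
            raise ValueError(f"non-finite coordinates in frame at t={self.time} ps")


@dataclass
class RelativeTrajectory:
    """Anchor-relative gas positions sampled at a constant stride.

    ``positions`` has shape ``(n_frames, n_molecules, 3)`` in Å relative to
    the anchor; ``times`` is in ps.  ``distances`` is always the Euclidean
    norm of ``positions`` along the last axis.
    """

    times: np.ndarray
    molecule_ids: list[str]
    positions: np.ndarray
    stride: float
    superposed: bool = False
    source: str | None = None
    _distances: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_molecules, 3)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.positions.shape[1] != len(self.molecule_ids):
            raise ValueError("molecule_ids and positions disagree on molecule count")
        if len(self.times) >= 2:
            dts = np.diff(self.times)
            if np.any(dts <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dts, self.stride, rtol=0, atol=1e-6):
                raise ValueError("frame spacing does not match declared stride")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[1]

    @property
    def distances(self) -> np.ndarray:
        """Per-frame, per-molecule distance to the anchor (Å)."""
        if self._distances is None:
            self._distances = np.linalg.norm(self.positions, axis=2)
        return self._distances

    def molecule_index(self, molecule_id: str) -> int:
        return self.molecule_ids.index(molecule_id)

    def decimate(self, factor: int) -> "RelativeTrajectory":
        """Keep every ``factor``-th frame (stride multiplies by ``factor``)."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("decimation factor must be a positive integer")
        return RelativeTrajectory(
            times=self.times[::factor],
            molecule_ids=list(self.molecule_ids),
            positions=self.positions[::factor],
            stride=self.stride * factor,
            superposed=self.superposed,
            source=self.source,
        )


@dataclass
class Residue:
    """A (pseudo-)residue: id, human label and its atom coordinates (Å)."""

    residue_id: str
    label: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))


@dataclass
class EnvironmentModel:
    """Residues lining the gas pathways plus named pathway-signature regions."""

    residues: list[Residue]
    regions: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.residue_id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise ValueError("residue ids must be unique")
        known = set(ids)
        for name, members in self.regions.items():
            missing = set(members) - known
            if missing:
                raise ValueError(f"region {name!r} references unknown residues {sorted(missing)}")

    def residue(self, residue_id: str) -> Residue:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        raise KeyError(residue_id)

    @property
    def atom_coords(self) -> np.ndarray:
        """All atoms stacked, shape (n_atoms, 3)."""
        return np.vstack([r.coords for r in self.residues])

    @property
    def atom_residue_index(self) -> np.ndarray:
        """For each stacked atom, the index of its residue in ``residues``."""
        return np.concatenate(
            [np.full(len(r.coords), i) for i, r in enumerate(self.residues)]
        )


# stationary-probability display classes, from high to low
_PI_CLASSES = (("red", 0.40), ("blue", 0.10), ("orange", 0.01))


def classify_pi(pi: float) -> str:
    """Display class for a stationary probability: red / blue / orange / excluded."""
    for name, thr in _PI_CLASSES:
        if pi > thr:
            return name
    return "excluded"


@dataclass
class StateCloud:
    """Grid points near the anchor with their stationary probabilities."""

    coords: np.ndarray
    pi: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < 0):
            raise ValueError("stationary probabilities must be nonnegative")


# ---------------------------------------------------------------------------
# trajectory reading / writing


def _parse_columnar(path: str) -> list[Frame]:
    stride = None
    molecule_ids: list[str] | None = None
    rows: dict[float, dict[str, np.ndarray]] = {}
    order: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("stride_ps:"):
                    stride = float(body.split(":", 1)[1])
                elif body.startswith("molecules:"):
                    molecule_ids = body.split(":", 1)[1].split()
                continue
            parts = line.split()
            if len(parts) != 5:
                raise TrajectoryParseError(
                    f"{path}:{lineno}: expected 5 columns (time id x y z), got {len(parts)}"
                )
            try:
                t = float(parts[0])
                xyz = np.array([float(p) for p in parts[2:5]])
            except ValueError as exc:
                raise TrajectoryParseError(f"{path}:{lineno}: {exc}") from None
            if t not in rows:
                rows[t] = {}
                order.append(t)
            rows[t][parts[1]] = xyz
    if len(order) < 2:
        raise TrajectoryParseError(f"{path}: need at least 2 frames, got {len(order)}")
    if any(b <= a for a, b in zip(order, order[1:])):
        raise TrajectoryParseError(f"{path}: frame times are not strictly increasing")

    frames: list[Frame] = []
    for t in order:
        entries = rows[t]
        anchor = entries.pop(ANCHOR_ID, np.zeros(3))
        ref_keys = sorted(k for k in entries if k.startswith(REF_PREFIX))
        ref = np.array([entries.pop(k) for k in ref_keys]) if ref_keys else None
        gas = dict(entries)
        if molecule_ids is not None and set(gas) != set(molecule_ids):
            raise TrajectoryParseError(
                f"{path}: frame at t={t} ps does not contain the declared molecules"
            )
        frames.append(Frame(t, gas, anchor, ref))
    counts = {len(f.gas_positions) for f in frames}
    if len(counts) != 1:
        raise TrajectoryParseError(f"{path}: molecule count varies across frames")
    if stride is not None and len(frames) >= 2:
        if not math.isclose(frames[1].time - frames[0].time, stride, abs_tol=1e-6):
            warnings.warn(f"{path}: declared stride {stride} ps differs from frame spacing")
    return frames


def _parse_xyz(path: str) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise TrajectoryParseError(f"{path}:{i + 1}: expected atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        for tok in comment.replace(",", " ").split():
            if tok.startswith("t="):
                t = float(tok[2:].rstrip("ps"))
        if t is None:
            t = float(len(frames))
        gas: dict[str, np.ndarray] = {}
        anchor = np.zeros(3)
        gi = 0
        for j in range(natoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise TrajectoryParseError(f"{path}: truncated frame at line {lineno + 1}")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise TrajectoryParseError(f"{path}:{lineno + 1}: expected 'element x y z'")
            try:
                xyz = np.array([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise TrajectoryParseError(f"{path}:{lineno + 1}: {exc}") from None
            if parts[0].capitalize() == "Fe":
                anchor = xyz
            else:
                gas[f"{parts[0]}_{gi:04d}"] = xyz
                gi += 1
        frames.append(Frame(t, gas, anchor))
        i += 2 + natoms
    if len(frames) < 2:
        raise TrajectoryParseError(f"{path}: need at least 2 frames, got {len(frames)}")
    times = [f.time for f in frames]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise TrajectoryParseError(f"{path}: frame times are not strictly increasing")
    counts = {len(f.gas_positions) for f in frames}
    if len(counts) != 1:
        raise TrajectoryParseError(f"{path}: molecule count varies across frames")
    return frames


def load_trajectory(path: str, format: str = "columnar") -> list[Frame]:
    """Read a trajectory file into time-ordered :class:`Frame` objects.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"columnar"`` (native format) or ``"xyz"``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "columnar":
        return _parse_columnar(path)
    if format == "xyz":
        return _parse_xyz(path)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(traj: RelativeTrajectory, path: str) -> None:
    """Write a relative trajectory in the native columnar format.

    The anchor is written at the origin (coordinates are anchor-relative).
    """
    with open(path, "w") as fh:
        fh.write("# gasport trajectory v1\n")
        fh.write(f"# stride_ps: {traj.stride:g}\n")
        fh.write(f"# molecules: {' '.join(traj.molecule_ids)}\n")
        fh.write("# columns: time_ps id x y z\n")
        for fi, t in enumerate(traj.times):
            fh.write(f"{t:.6f} {ANCHOR_ID} 0.0 0.0 0.0\n")
            for mi, mid in enumerate(traj.molecule_ids):
                x, y, z = traj.positions[fi, mi]
                fh.write(f"{t:.6f} {mid} {x:.6f} {y:.6f} {z:.6f}\n")


def write_xyz(traj: RelativeTrajectory, path: str) -> None:
    """Write a relative trajectory as XYZ (anchor as Fe at the origin)."""
    with open(path, "w") as fh:
        for fi, t in enumerate(traj.times):
            fh.write(f"{traj.n_molecules + 1}\n")
            fh.write(f"t={t:.6f} ps\n")
            fh.write("Fe 0.000000 0.000000 0.000000\n")
            for mi in range(traj.n_molecules):
                x, y, z = traj.positions[fi, mi]
                fh.write(f"O {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# superposition


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid fit: returns (R, t) with R @ x + t ≈ target."""
    mob_c = mobile.mean(axis=0)
    tgt_c = target.mean(axis=0)
    H = (mobile - mob_c).T @ (target - tgt_c)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt_c - R @ mob_c
    return R, t


def _check_reference_atoms(ref: np.ndarray) -> None:
    if ref is None or len(ref) < 3:
        raise SuperpositionError("superposition needs at least 3 reference atoms")
    centered = ref - ref.mean(axis=0)
    # rank < 2 means the atoms are collinear (or coincident)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise SuperpositionError("reference atoms are collinear; fit is underdetermined")


def superpose_and_center(
    frames: list[Frame], reference: Frame | None = None
) -> RelativeTrajectory:
    """Superpose frames onto a reference and express gas positions anchor-relative.

    If the frames carry ``reference_atoms``, each frame is rigid-body fitted
    (Kabsch, equal weights) onto the reference frame's atoms before
    centering; otherwise positions are used as-is (pass-through centering).
    The output positions are ``gas - anchor`` in the reference orientation.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    reference = frames[0] if reference is None else reference
    molecule_ids = sorted(frames[0].gas_positions)
    for f in frames:
        if sorted(f.gas_positions) != molecule_ids:
            raise ValueError("molecule ids are not constant across frames")

    do_fit = reference.reference_atoms is not None and all(
        f.reference_atoms is not None for f in frames
    )
    if do_fit:
        _check_reference_atoms(reference.reference_atoms)

    n_frames, n_mol = len(frames), len(molecule_ids)
    positions = np.empty((n_frames, n_mol, 3))
    times = np.empty(n_frames)
    for fi, f in enumerate(frames):
        times[fi] = f.time
        gas = np.array([f.gas_positions[m] for m in molecule_ids])
        anchor = f.anchor_position
        if do_fit:
            R, t = _kabsch(f.reference_atoms, reference.reference_atoms)
            gas = gas @ R.T + t
            anchor = R @ anchor + t
        positions[fi] = gas - anchor

    if n_frames >= 2:
        strides = np.diff(times)
        stride = float(strides[0])
        if not np.allclose(strides, stride, atol=1e-6):
            raise ValueError("frames are not uniformly spaced in time")
    return RelativeTrajectory(
        times=times,
        molecule_ids=molecule_ids,
        positions=positions,
        stride=stride,
        superposed=do_fit,
    )


# ---------------------------------------------------------------------------
# environment PDB


def read_environment_pdb(path: str, regions: dict[str, set[str]] | None = None) -> EnvironmentModel:
    """Read residues and atom coordinates from a PDB file via gemmi.

    Residue ids are ``<name><seqid>`` (e.g. ``TRP389``); waters and the
    anchor metal are kept too (callers can exclude them via region choices).
    """
    import gemmi

    structure = gemmi.read_structure(path)
    residues: list[Residue] = []
    seen: set[str] = set()
    for model in structure:
        for chain in model:
            for res in chain:
                rid = f"{res.name}{res.seqid.num}"
                if len(structure) > 1 or rid in seen:
                    rid = f"{chain.name}:{rid}"
                seen.add(rid)
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
                residues.append(Residue(rid, res.name, coords))
        break  # first model only
    return EnvironmentModel(residues, regions or {})


# ---------------------------------------------------------------------------
# state-cloud export


def export_state_cloud(
    model,
    grid,
    radius_max: float = 20.0,
    path: str | None = None,
    drop_excluded: bool = True,
) -> StateCloud:
    """Turn an MSM stationary distribution into a point cloud near the anchor.

    One pseudo-atom per active state within ``radius_max`` Å of the anchor;
    π is renormalized over the included states, written to the PDB B-factor
    column scaled ×100 and clamped to [0, 999.99].  States with π < 0.01 are
    dropped when ``drop_excluded`` is true (they can be kept for debugging).
    """
    if radius_max <= 0:
        raise ValueError("radius_max must be positive")
    if model.pi is None:
        raise ValueError("model has no stationary distribution")
    coords = grid.state_coords(np.asarray(model.active_states))
    dist = np.linalg.norm(coords, axis=1)
    keep = dist <= radius_max
    coords, pi = coords[keep], np.asarray(model.pi)[keep]
    if pi.sum() > 0:
        pi = pi / pi.sum()
    classes = [classify_pi(p) for p in pi]
    if drop_excluded:
        inc = np.array([c != "excluded" for c in classes], dtype=bool)
        coords, pi = coords[inc], pi[inc]
        classes = [c for c in classes if c != "excluded"]
    if len(pi) == 0:
        warnings.warn("state cloud is empty after filtering")
    cloud = StateCloud(coords.reshape(-1, 3), pi, classes)
    if path is not None:
        _write_cloud_pdb(cloud, path)
    return cloud


def write_environment_pdb(env: EnvironmentModel, path: str) -> None:
    """Write an environment model as PDB HETATM pseudo-atoms (one per atom)."""
    with open(path, "w") as fh:
        fh.write("REMARK   gasport environment model\n")
        serial = 0
        for ri, res in enumerate(env.residues, start=1):
            name = (res.label or "UNK")[:3].upper().ljust(3)
            for xyz in res.coords:
                serial += 1
                x, y, z = xyz
                fh.write(
                    f"HETATM{serial % 100000:5d}  X   {name} A{ri % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           X\n"
                )
        fh.write("END\n")


def _write_cloud_pdb(cloud: StateCloud, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("REMARK   gasport MSM state cloud; B-factor = 100 * stationary probability\n")
        for i, (xyz, p) in enumerate(zip(cloud.coords, cloud.pi), start=1):
            serial = i % 100000
            b = min(max(100.0 * p, 0.0), 999.99)
            x, y, z = xyz
            fh.write(
                f"HETATM{serial:5d}  X   STA A{(i % 10000):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}           X\n"
            )
        fh.write("END\n")
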