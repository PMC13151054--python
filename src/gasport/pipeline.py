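"""End-to-end orchestration: simulate/ingest → events → contacts → MSM → kinetics.

A run is driven by a single TOML config; every run writes the resolved
configuration (with defaults filled in) and a config hash next to its
outputs, so any artifact can be traced to the exact settings that produced
it.  Stages are individually callable; a stage failure raises
:class:`StageError` naming the stage, with earlier outputs left on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .contact_pathways import (
    PathwayDefinition,
    aggregate_table,
    classify_all,
    contact_frequencies,
    overlap_and_samepath,
    trapped_filter,
)
from .diffusion_msd import msd_alpha
from .event_tracing import EventThresholds, detect_events, events_dataframe, summarize_events
from .grid_msm import (
    GridSpec,
    assign_states,
    chapman_kolmogorov,
    core_sets_by_distance,
    estimate_msm,
    implied_timescales,
    reduce_milestoning,
    restrict_to_events,
    select_source_sink,
)
from .io_model import (
    export_state_cloud,
    load_trajectory,
    read_environment_pdb,
    superpose_and_center,
    write_environment_pdb,
    write_trajectory,
)
from .kinetics_tpt import compute_tpt_rate
from .synthetic_gas import BrownianParams, SyntheticSystem, WellSpec, simulate_brownian

log = logging.getLogger("gasport")

STAGES = ("simulate", "detect", "classify", "msm", "kinetics", "msd", "all")


def _write_tsv(df: pd.DataFrame, path, chash: str, index: bool = False) -> None:
    """Write a TSV with a leading config-hash comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, sep="\t", index=index)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Resolved run configuration; defaults follow the standard protocol.

    Thresholds: 6.0 Å inner / 20.0 Å outer event cutoffs at 10 ps analysis
    stride; 6.7 Å sink / 22 Å source for the MSM at 100 ps stride on a
    1 Å grid over a 40 Å cube; 3.5 Å contact cutoff; 75% trapped filter.
    """

    # input
    trajectory: str | None = None
    trajectory_format: str = "columnar"
    environment: str | None = None
    synthetic: dict | None = None
    # events
    r_inner: float = 6.0
    r_outer: float = 20.0
    analysis_stride: float = 10.0
    # contacts / pathways
    contact_cutoff: float = 3.5
    trapped_threshold: float = 0.75
    report_floor: float = 12.0
    pathways: dict[str, list[str]] = field(default_factory=dict)
    # msm
    grid_spacing: float = 1.0
    grid_half_edge: float = 20.0
    wrap_mode: str = "periodic"
    msm_stride: float = 100.0
    lags: list[float] = field(default_factory=lambda: [100.0, 200.0, 500.0, 1000.0, 2000.0, 5000.0])
    r_sink: float = 6.7
    r_source: float = 22.0
    restrict_msm_to_events: bool = True
    # misc
    seed: int = 0
    output_dir: str = "gasport_out"

    def validate(self) -> None:
        if self.r_inner >= self.r_outer:
            raise ValueError("r_inner must be smaller than r_outer")
        if self.r_sink >= self.r_source:
            raise ValueError("r_sink must be smaller than r_source")
        if self.trajectory is None and self.synthetic is None:
            raise ValueError("config needs either an input trajectory or a [synthetic] block")
        GridSpec(self.grid_spacing, self.grid_half_edge, self.wrap_mode)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTION_KEYS = {
    "input": {"trajectory": "trajectory", "format": "trajectory_format",
              "environment": "environment"},
    "events": {"r_inner": "r_inner", "r_outer": "r_outer", "stride": "analysis_stride"},
    "contacts": {"cutoff": "contact_cutoff", "trapped_threshold": "trapped_threshold",
                 "report_floor": "report_floor"},
    "msm": {"spacing": "grid_spacing", "half_edge": "grid_half_edge",
            "wrap_mode": "wrap_mode", "stride": "msm_stride", "lags": "lags",
            "r_sink": "r_sink", "r_source": "r_source",
            "restrict_to_events": "restrict_msm_to_events"},
    "run": {"seed": "seed", "output_dir": "output_dir"},
}


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run config (documented keys; unknown keys rejected)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig()
    for section, mapping in _SECTION_KEYS.items():
        block = raw.pop(section, {})
        for key, value in block.items():
            if key not in mapping:
                raise ValueError(f"unknown key {key!r} in [{section}]")
            setattr(cfg, mapping[key], value)
    if "synthetic" in raw:
        cfg.synthetic = raw.pop("synthetic")
    if "pathways" in raw:
        cfg.pathways = {k: list(v) for k, v in raw.pop("pathways").items()}
    if raw:
        raise ValueError(f"unknown config sections: {sorted(raw)}")
    cfg.validate()
    return cfg


def _synthetic_inputs(cfg: RunConfig):
    blk = dict(cfg.synthetic or {})
    wells = tuple(
        WellSpec(
            w.get("id", f"W{i + 1}"),
            tuple(w["center"]),
            w.get("radius", 4.0),
            w.get("depth", 3.0),
            n_lining=int(w.get("n_lining", 12)),
        )
        for i, w in enumerate(blk.get("wells", []))
    )
    system = SyntheticSystem(
        box_half_edge=float(blk.get("box_half_edge", 20.0)),
        wells=wells,
        sink_radius=float(blk.get("sink_radius", 6.0)),
    )
    params = BrownianParams(
        n_molecules=int(blk.get("n_molecules", 100)),
        n_steps=int(blk.get("n_steps", 100_000)),
        diffusion_coefficient=float(blk.get("diffusion_coefficient", 1.0)),
        dt=float(blk.get("dt", 0.01)),
        save_stride=float(blk.get("save_stride", cfg.analysis_stride)),
        seed=int(blk.get("seed", cfg.seed)),
    )
    return system, params


def run_pipeline(cfg: RunConfig, until: str = "all") -> dict:
    """Execute the pipeline through stage ``until``; returns collected results.

    Outputs land in ``cfg.output_dir``: the event table, contact tables (raw
    and trapped-filtered), overlap/same-path tables, MSM state table and
    sparse transition matrix, implied-timescale report, kinetics report, MSD
    summary, state-cloud PDB, and the resolved config.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash
    with open(out / "resolved_config.json", "w") as fh:
        json.dump({"config_hash": chash, "version": __version__, **cfg.to_dict()}, fh, indent=2)
    results: dict = {"config_hash": chash}
    timings: dict[str, float] = {}

    def stage_done(name: str, t0: float) -> bool:
        timings[name] = time.time() - t0
        log.info("stage %s done in %.1f s", name, timings[name])
        return until == name

    # --- simulate / ingest
    t0 = time.time()
    try:
        environment = None
        if cfg.trajectory is not None:
            frames = load_trajectory(cfg.trajectory, cfg.trajectory_format)
            traj = superpose_and_center(frames)
            if cfg.environment:
                environment = read_environment_pdb(cfg.environment)
        else:
            system, params = _synthetic_inputs(cfg)
            traj = simulate_brownian(system, params)
            environment = system.environment()
            write_trajectory(traj, str(out / f"synthetic_traj_{chash}.dat"))
            write_environment_pdb(environment, str(out / "environment.pdb"))
        results["n_frames"] = traj.n_frames
        results["n_molecules"] = traj.n_molecules
    except Exception as exc:
        raise StageError("simulate", exc) from exc
    if stage_done("simulate", t0):
        return _finish(results, timings, out)

    # --- detect events
    t0 = time.time()
    try:
        analysis_traj = traj
        if cfg.analysis_stride > traj.stride:
            analysis_traj = traj.decimate(int(round(cfg.analysis_stride / traj.stride)))
        thresholds = EventThresholds(cfg.r_inner, cfg.r_outer, analysis_traj.stride)
        events = detect_events(analysis_traj, thresholds)
        total_us = (analysis_traj.times[-1] - analysis_traj.times[0]) / 1e6
        results["events"] = summarize_events(events, total_us, traj.n_molecules)
        results["n_events"] = len(events)
    except Exception as exc:
        raise StageError("detect", exc) from exc
    if stage_done("detect", t0):
        _write_tsv(events_dataframe(events), out / "events.tsv", chash)
        return _finish(results, timings, out)

    # --- classify contacts / pathways
    t0 = time.time()
    try:
        profile = None
        if environment is not None and events:
            profile = contact_frequencies(
                events, analysis_traj, environment,
                cutoff=cfg.contact_cutoff, report_floor=cfg.report_floor,
            )
            defs = [
                PathwayDefinition(label, frozenset(sig), priority=i)
                for i, (label, sig) in enumerate(
                    (cfg.pathways or {k: sorted(v) for k, v in environment.regions.items()}).items()
                )
            ]
            if defs:
                classify_all(events, profile, defs)
            starred = trapped_filter(profile, cfg.trapped_threshold)
            _write_tsv(profile.per_pair, out / "contacts_raw.tsv", chash)
            _write_tsv(aggregate_table(profile), out / "contacts_table.tsv", chash)
            _write_tsv(aggregate_table(starred), out / "contacts_table_starred.tsv", chash)
            overlap, samepath = overlap_and_samepath(events)
            _write_tsv(overlap, out / "overlap.tsv", chash, index=True)
            _write_tsv(samepath, out / "samepath.tsv", chash)
            results["same_path"] = samepath.to_dict("records")
        _write_tsv(events_dataframe(events), out / "events.tsv", chash)
    except Exception as exc:
        raise StageError("classify", exc) from exc
    if stage_done("classify", t0):
        return _finish(results, timings, out)

    # --- discretize + MSM
    t0 = time.time()
    try:
        grid = GridSpec(cfg.grid_spacing, cfg.grid_half_edge, cfg.wrap_mode)
        msm_stride = min(cfg.msm_stride, traj.stride * (traj.n_frames // 4) or traj.stride)
        dtraj = assign_states(traj, grid, stride=max(msm_stride, traj.stride))
        dtraj_events = restrict_to_events(dtraj, events) if (cfg.restrict_msm_to_events and events) else dtraj
        lags = [l for l in cfg.lags if l / dtraj.stride >= 1 and l / dtraj.stride < dtraj.n_frames / 2]
        if not lags:
            lags = [dtraj.stride]
        model = estimate_msm(dtraj_events, lag=lags[0])
        results["msm"] = {"lag_ps": lags[0], "n_active_states": model.n_active}
        if len(lags) >= 2:
            its = implied_timescales(dtraj_events, lags, k=3)
            _write_tsv(
                pd.DataFrame(
                    its.timescales, index=pd.Index(its.lags, name="lag_ps"),
                    columns=[f"t{k + 2}" for k in range(its.timescales.shape[1])],
                ),
                out / "implied_timescales.tsv", chash, index=True,
            )
        _write_ck_report(dtraj_events, lags[0], out, chash, cfg.seed, results)
        _write_msm(model, grid, out, chash)
        export_state_cloud(model, grid, radius_max=cfg.grid_half_edge,
                           path=str(out / "state_cloud.pdb"))
    except Exception as exc:
        raise StageError("msm", exc) from exc
    if stage_done("msm", t0):
        return _finish(results, timings, out)

    # --- kinetics
    t0 = time.time()
    try:
        source, sink = select_source_sink(
            dtraj_events, events, r_sink=cfg.r_sink, r_source=cfg.r_source
        )
        # strict boundary-frame states can fall outside the connected set on
        # sparse data; fall back to the active states in the outer shell band
        act_dist = grid.state_distances(model.active_states)
        if (model.local_index(source) < 0).all():
            source = model.active_states[act_dist >= cfg.r_source - 2 * grid.spacing]
            log.warning("source boundary states disconnected; using %d outer-shell states",
                        len(source))
        if (model.local_index(sink) < 0).all():
            sink = model.active_states[act_dist < cfg.r_sink]
            log.warning("sink states disconnected; using %d active sink-shell states",
                        len(sink))
        tpt = compute_tpt_rate(model, source, sink)
        results["kinetics"] = {
            "n_source": len(source),
            "n_sink": len(sink),
            "mfpt_ns": tpt.mfpt_ns,
            "tpt_rate_per_ps": tpt.rate,
            "rate_mfpt_ns": tpt.rate_mfpt_ns,
            "lag_ps": model.lag,
        }
        _write_kinetics(tpt, model, grid, out, chash)
    except Exception as exc:
        raise StageError("kinetics", exc) from exc
    if stage_done("kinetics", t0):
        return _finish(results, timings, out)

    # --- MSD
    t0 = time.time()
    try:
        msd = msd_alpha(traj)
        results["msd"] = {"alpha": msd.alpha, "alpha_se": msd.alpha_se,
                          "fit_window_ps": list(msd.fit_window)}
        _write_tsv(pd.DataFrame({"lag_ps": msd.lags, "msd_A2": msd.msd}),
                   out / "msd.tsv", chash)
    except Exception as exc:
        raise StageError("msd", exc) from exc
    stage_done("msd", t0)
    return _finish(results, timings, out)


def _write_ck_report(dtraj, base_lag: float, out: Path, chash: str,
                     seed: int, results: dict) -> None:
    """Chapman-Kolmogorov test on the milestoning-reduced core model.

    Cores are the event states within 7 Å of the metal versus everything
    beyond; the reduced chain keeps Bayesian sampling affordable.
    """
    try:
        cores = [c for c in core_sets_by_distance(dtraj, radii=(7.0,)) if len(c)]
        if len(cores) < 2:
            return
        reduced = reduce_milestoning(dtraj, cores)
        max_k = max(1, int(reduced.n_frames * reduced.stride / (2 * base_lag)))
        steps = tuple(k for k in (1, 2, 3, 4, 5) if k <= max_k)
        ck = chapman_kolmogorov(reduced, base_lag=base_lag, steps=steps,
                                n_sets=2, n_samples=50, seed=seed)
        rows = []
        for si in range(len(ck.sets)):
            for ki, k in enumerate(ck.steps):
                rows.append({"set": si, "k": int(k),
                             "predicted": ck.predicted[ki, si],
                             "estimated": ck.estimated[ki, si],
                             "ci_lower": ck.ci_lower[ki, si],
                             "ci_upper": ck.ci_upper[ki, si]})
        _write_tsv(pd.DataFrame(rows), out / "ck_report.tsv", chash)
        results["ck_passed"] = ck.passed
    except (ValueError, RuntimeError) as exc:
        log.warning("CK report skipped: %s", exc)


def _write_msm(model, grid, out: Path, chash: str) -> None:
    coords = grid.state_coords(model.active_states)
    dist = grid.state_distances(model.active_states)
    state_df = pd.DataFrame(
        {
            "state": model.active_states,
            "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
            "distance_A": dist, "pi": model.pi,
        }
    )
    _write_tsv(state_df, out / "state_table.tsv", chash)
    T = model.transition_matrix.tocoo()
    with open(out / "transition_matrix.coo", "w") as fh:
        fh.write(f"# config_hash: {chash}\n")
        fh.write(f"# lag_ps {model.lag}; row col prob over active-state indices\n")
        for i, j, v in zip(T.row, T.col, T.data):
            fh.write(f"{i} {j} {v:.10g}\n")


def _write_kinetics(tpt, model, grid, out: Path, chash: str) -> None:
    flux = tpt.flux.tocoo()
    order = np.argsort(-flux.data)[:20]
    src_states = model.active_states[flux.row[order]]
    dst_states = model.active_states[flux.col[order]]
    src_xyz = grid.state_coords(src_states)
    dst_xyz = grid.state_coords(dst_states)
    top = pd.DataFrame(
        {
            "from_state": src_states,
            "from_x": src_xyz[:, 0], "from_y": src_xyz[:, 1], "from_z": src_xyz[:, 2],
            "to_state": dst_states,
            "to_x": dst_xyz[:, 0], "to_y": dst_xyz[:, 1], "to_z": dst_xyz[:, 2],
            "flux": flux.data[order],
        }
    )
    with open(out / "kinetics_report.txt", "w") as fh:
        fh.write(f"# config_hash {chash}\n")
        fh.write(f"lag_ps\t{tpt.lag}\nestimator\t{tpt.estimator}\n")
        fh.write(f"n_source\t{len(tpt.source)}\nn_sink\t{len(tpt.sink)}\n")
        fh.write(f"mfpt_ns\t{tpt.mfpt_ns:.6g}\nrate_per_ps\t{tpt.rate:.6g}\n")
        fh.write(f"rate_mfpt_ns\t{tpt.rate_mfpt_ns:.6g}\n\ntop flux-carrying transitions:\n")
        fh.write(top.to_string(index=False))
        fh.write("\n")


def _finish(results: dict, timings: dict, out: Path) -> dict:
    results["stage_timings_s"] = timings
    with open(out / "run_report.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=2)
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    return obj
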