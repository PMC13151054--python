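"""Detection and tracing of catalytic-zone access/egress events.

An *event* is one traced excursion of a gas molecule between the outer shell
(``r_outer``, default 20 Å from the catalytic metal) and the inner catalytic
cutoff (``r_inner``, default 6 Å).  For every maximal dwell below the inner
cutoff the trajectory is traced backward to the last frame beyond the outer
shell (the entry) and forward to the first frame beyond it (the exit).  Two
sub-cutoff dwells separated by an excursion that never reaches the outer
shell count as a single dwell — rattling at the cutoff is not double-counted.
Dwells with no outer-shell crossing before (after) the trajectory start (end)
yield censored entries (exits): counted, but excluded from time averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import RelativeTrajectory

__all__ = [
    "EventThresholds",
    "EventRecord",
    "detect_events",
    "summarize_events",
    "rate_summary",
    "events_dataframe",
]


@dataclass(frozen=True)
class EventThresholds:
    """Distance cutoffs (Å) and analysis stride (ps)."""

    r_inner: float = 6.0
    r_outer: float = 20.0
    stride: float = 10.0

    def __post_init__(self) -> None:
        if self.r_inner >= self.r_outer:
            raise ValueError("r_inner must be smaller than r_outer")


@dataclass
class EventRecord:
    """One traced entry or exit.

    ``t_outer`` is the boundary frame time (last beyond the outer shell
    before the dwell for entries; first beyond it after the dwell for
    exits); ``t_inner`` is the first (entry) or last (exit) frame below the
    inner cutoff.  ``duration`` is |t_inner − t_outer| in ns.  Events whose
    tracing runs off the trajectory end are censored (``t_outer`` then falls
    back to the trajectory boundary frame and duration is undefined).
    """

    molecule_id: str
    direction: str  # "entry" | "exit"
    dwell_id: int
    t_outer: float  # ps
    t_inner: float  # ps
    min_distance: float  # Å over the dwell
    frame_span: tuple[int, int]  # inclusive frame indices, outer..inner order-agnostic
    censored: bool = False
    pathway_label: str | None = None

    @property
    def duration(self) -> float | None:
        """Traced duration in ns; None when censored."""
        if self.censored:
            return None
        return abs(self.t_inner - self.t_outer) / 1000.0

    @property
    def span_times(self) -> tuple[float, float]:
        """Time span (ps) covered by the traced segment, ordered."""
        lo, hi = sorted((self.t_outer, self.t_inner))
        return lo, hi


def _dwell_segments(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, stop) index pairs."""
    idx = np.flatnonzero(below)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_events(
    traj: RelativeTrajectory, thresholds: EventThresholds | None = None
) -> list[EventRecord]:
    """Detect and trace all access/egress events in a trajectory.

    Returns one entry and one exit :class:`EventRecord` per merged dwell,
    in (molecule, time) order.  Entry and exit of the same dwell share a
    ``dwell_id``.
    """
    thresholds = thresholds or EventThresholds()
    r_in, r_out = thresholds.r_inner, thresholds.r_outer
    d = traj.distances
    times = traj.times
    events: list[EventRecord] = []
    dwell_id = 0
    for mi, mid in enumerate(traj.molecule_ids):
        dm = d[:, mi]
        segments = _dwell_segments(dm < r_in)
        if not segments:
            continue
        # merge dwells not separated by an outer-shell crossing
        merged = [segments[0]]
        for s, e in segments[1:]:
            prev_s, prev_e = merged[-1]
            if np.all(dm[prev_e + 1 : s] <= r_out):
                merged[-1] = (prev_s, e)
            else:
                merged.append((s, e))
        for s, e in merged:
            min_d = float(dm[s : e + 1].min())
            # backward trace for the entry
            before = np.flatnonzero(dm[:s] > r_out)
            if len(before):
                b = int(before[-1])
                entry = EventRecord(mid, "entry", dwell_id, times[b], times[s],
                                    min_d, (b, s))
            else:
                entry = EventRecord(mid, "entry", dwell_id, times[0], times[s],
                                    min_d, (0, s), censored=True)
            # forward trace for the exit
            after = np.flatnonzero(dm[e + 1 :] > r_out)
            if len(after):
                a = int(after[0]) + e + 1
                exit_ = EventRecord(mid, "exit", dwell_id, times[a], times[e],
                                    min_d, (e, a))
            else:
                last = len(dm) - 1
                exit_ = EventRecord(mid, "exit", dwell_id, times[last], times[e],
                                    min_d, (e, last), censored=True)
            events.extend([entry, exit_])
            dwell_id += 1
    return events


def rate_summary(n_events: int, total_time_us: float, n_molecules: int) -> dict:
    """Aggregate rate arithmetic for an event tally.

    Returns events/μs, the mean inter-event interval in ns, and the mean
    interval per molecule in μs (``n_molecules × total_time / n_events``).
    """
    if n_events == 0:
        return {
            "events_per_us": 0.0,
            "interevent_ns": float("inf"),
            "per_molecule_interval_us": float("inf"),
            "zero_events": True,
        }
    return {
        "events_per_us": n_events / total_time_us,
        "interevent_ns": total_time_us * 1000.0 / n_events,
        "per_molecule_interval_us": n_molecules * total_time_us / n_events,
        "zero_events": False,
    }


def summarize_events(
    events: list[EventRecord], total_time_us: float, n_molecules: int
) -> dict:
    """Event tallies, mean entry/exit times and aggregate rates.

    Mean times (ns) exclude censored events; censored events are counted
    separately.  Per-pathway tables cover whatever ``pathway_label`` values
    the events carry (``None`` grouped as ``"unassigned"``).
    """
    rows = []
    for ev in events:
        rows.append(
            {
                "pathway": ev.pathway_label or "unassigned",
                "direction": ev.direction,
                "duration_ns": ev.duration,
                "censored": ev.censored,
            }
        )
    df = pd.DataFrame(rows, columns=["pathway", "direction", "duration_ns", "censored"])
    n_total = len(df)
    summary = {
        "n_events": n_total,
        "n_censored": int(df["censored"].sum()) if n_total else 0,
        **rate_summary(n_total, total_time_us, n_molecules),
    }
    if n_total:
        ok = df[~df["censored"]]
        counts = (
            df.groupby(["pathway", "direction"]).size().unstack(fill_value=0)
        )
        means = (
            ok.groupby(["pathway", "direction"])["duration_ns"].mean().unstack()
        )
        summary["counts"] = counts
        summary["mean_times_ns"] = means
        summary["mean_entry_ns"] = float(
            ok[ok["direction"] == "entry"]["duration_ns"].mean()
        ) if (ok["direction"] == "entry").any() else float("nan")
        summary["mean_exit_ns"] = float(
            ok[ok["direction"] == "exit"]["duration_ns"].mean()
        ) if (ok["direction"] == "exit").any() else float("nan")
    return summary


def events_dataframe(events: list[EventRecord], system: str = "") -> pd.DataFrame:
    """One row per event, suitable for the delimited event report."""
    return pd.DataFrame(
        [
            {
                "system": system,
                "molecule": ev.molecule_id,
                "dwell": ev.dwell_id,
                "direction": ev.direction,
                "t_outer_ps": ev.t_outer,
                "t_inner_ps": ev.t_inner,
                "duration_ns": ev.duration,
                "min_distance_A": ev.min_distance,
                "pathway": ev.pathway_label or "unassigned",
                "censored": ev.censored,
            }
            for ev in events
        ]
    )
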