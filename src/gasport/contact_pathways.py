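"""Residue-contact profiles, the trapped-molecule filter and pathway labels.

A frame counts as a *contact* between an event's gas molecule and a residue
when any atom of the residue lies within the cutoff (default 3.5 Å) of any
gas-particle site.  Contact frequency is reported in contacts per nanosecond
of traced event time; the contact *fraction* (time in contact / event time)
drives the trapped filter: when a single residue is contacted for more than
75% of an event, that specific residue/event pair is removed from the
filtered ("starred") tables — the event itself is retained, as are its other
residue contacts.

Pathways are assigned by signature contact mass: an event gets the label of
the pathway definition whose signature residues accumulate the highest
summed contact frequency along the traced segment, with priority rank
breaking ties and ``"unassigned"`` for events that touch no signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .event_tracing import EventRecord
from .io_model import EnvironmentModel, RelativeTrajectory

__all__ = [
    "ContactProfile",
    "PathwayDefinition",
    "contact_frequencies",
    "trapped_filter",
    "classify_pathway",
    "classify_all",
    "overlap_and_samepath",
    "aggregate_table",
]

DEFAULT_CONTACT_CUTOFF = 3.5  # Å
DEFAULT_REPORT_FLOOR = 12.0  # contacts/ns, smallest value worth tabulating
DEFAULT_TRAPPED_THRESHOLD = 0.75


@dataclass
class ContactProfile:
    """Per (event, residue) contact statistics.

    ``per_pair`` columns: event_key (molecule_id, dwell_id, direction),
    residue_id, n_frames, frequency (contacts/ns), fraction of event time in
    contact.  ``event_index`` maps event keys back to their records.
    """

    per_pair: pd.DataFrame
    event_index: dict[tuple, EventRecord]
    cutoff: float
    report_floor: float
    stride_ps: float = 10.0
    trapped_filtered: bool = False

    def for_event(self, key: tuple) -> pd.DataFrame:
        return self.per_pair[self.per_pair["event_key"] == key]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway: signature residue set plus a tie-break priority."""

    label: str
    signature: frozenset
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.signature:
            raise ValueError(f"pathway {self.label!r} has an empty signature")


def _event_key(ev: EventRecord) -> tuple:
    return (ev.molecule_id, ev.dwell_id, ev.direction)


def contact_frequencies(
    events: list[EventRecord],
    traj: RelativeTrajectory,
    environment: EnvironmentModel,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    report_floor: float = DEFAULT_REPORT_FLOOR,
) -> ContactProfile:
    """Count residue contacts over every event's traced frame span.

    Environment atom coordinates must be in the same (anchor-relative)
    frame as the trajectory.  The raw profile retains all pairs; the report
    floor only governs the aggregated tables.
    """
    atoms = environment.atom_coords
    atom_res = environment.atom_residue_index
    res_ids = [r.residue_id for r in environment.residues]
    tree = cKDTree(atoms)
    mol_index = {m: i for i, m in enumerate(traj.molecule_ids)}
    rows = []
    index: dict[tuple, EventRecord] = {}
    for ev in events:
        mi = mol_index.get(ev.molecule_id)
        if mi is None:
            raise ValueError(f"event molecule {ev.molecule_id!r} not in trajectory")
        lo, hi = ev.frame_span
        lo, hi = min(lo, hi), max(lo, hi)
        if hi >= traj.n_frames:
            raise ValueError("event frame span exceeds trajectory length")
        key = _event_key(ev)
        index[key] = ev
        span_frames = hi - lo + 1
        span_ns = span_frames * traj.stride / 1000.0
        pos = traj.positions[lo : hi + 1, mi, :]
        neighbor_lists = tree.query_ball_point(pos, cutoff)
        counts: dict[int, int] = {}
        for nbrs in neighbor_lists:
            if not nbrs:
                continue
            for ri in set(atom_res[nbrs]):
                counts[int(ri)] = counts.get(int(ri), 0) + 1
        for ri, n in sorted(counts.items()):
            rows.append(
                {
                    "event_key": key,
                    "molecule": ev.molecule_id,
                    "direction": ev.direction,
                    "pathway": ev.pathway_label,
                    "residue_id": res_ids[ri],
                    "n_frames": n,
                    "frequency": n / span_ns,
                    "fraction": n / span_frames,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "event_key", "molecule", "direction", "pathway",
            "residue_id", "n_frames", "frequency", "fraction",
        ],
    )
    return ContactProfile(df, index, cutoff, report_floor, stride_ps=traj.stride)


def trapped_filter(
    profile: ContactProfile, threshold: float = DEFAULT_TRAPPED_THRESHOLD
) -> ContactProfile:
    """Starred variant: drop residue/event pairs with contact fraction > threshold.

    Each pair is judged independently; if two residues both exceed the
    threshold in one event, both pairs go and the event's remaining contacts
    stay.  The filter only removes rows, so every starred frequency is
    bounded by its unfiltered counterpart.
    """
    keep = profile.per_pair["fraction"] <= threshold
    return ContactProfile(
        profile.per_pair[keep].reset_index(drop=True),
        profile.event_index,
        profile.cutoff,
        profile.report_floor,
        stride_ps=profile.stride_ps,
        trapped_filtered=True,
    )


def aggregate_table(
    profile: ContactProfile, top: int = 10, floor: float | None = None
) -> pd.DataFrame:
    """Pathway × direction contact table (top residues by pooled frequency).

    Pooled frequency for a residue is total contacts over the group divided
    by total traced event time, in contacts/ns.  Entries below the report
    floor are omitted (the raw per-pair profile keeps everything).
    """
    floor = profile.report_floor if floor is None else floor
    df = profile.per_pair.copy()
    if df.empty:
        return pd.DataFrame(columns=["pathway", "direction", "residue_id", "frequency"])
    df["pathway"] = df["pathway"].fillna("unassigned")
    span_frames = {
        k: (abs(ev.frame_span[1] - ev.frame_span[0]) + 1)
        for k, ev in profile.event_index.items()
    }
    out = []
    for (pathway, direction), grp in df.groupby(["pathway", "direction"]):
        ev_keys = grp["event_key"].unique()
        # each event's traced span counts once toward the pooled time base
        total_ns = sum(span_frames[k] for k in ev_keys) * profile.stride_ps / 1000.0
        if total_ns == 0:
            continue
        pooled = grp.groupby("residue_id")["n_frames"].sum() / total_ns
        pooled = pooled[pooled >= floor].sort_values(ascending=False).head(top)
        for rid, freq in pooled.items():
            out.append(
                {"pathway": pathway, "direction": direction, "residue_id": rid,
                 "frequency": float(freq)}
            )
    return pd.DataFrame(out, columns=["pathway", "direction", "residue_id", "frequency"])


def classify_pathway(
    event: EventRecord,
    profile: ContactProfile,
    definitions: list[PathwayDefinition],
) -> str:
    """Label one event by maximal summed signature contact frequency."""
    if not definitions:
        raise ValueError("no pathway definitions supplied")
    pairs = profile.for_event(_event_key(event))
    freq = dict(zip(pairs["residue_id"], pairs["frequency"]))
    best_label, best_mass, best_priority = "unassigned", 0.0, None
    for d in sorted(definitions, key=lambda d: d.priority):
        mass = sum(freq.get(r, 0.0) for r in d.signature)
        if mass > 0 and (best_priority is None or mass > best_mass + 1e-12):
            best_label, best_mass, best_priority = d.label, mass, d.priority
    return best_label


def classify_all(
    events: list[EventRecord],
    profile: ContactProfile,
    definitions: list[PathwayDefinition],
) -> list[EventRecord]:
    """Assign pathway labels in place (and in the profile); returns the events."""
    for ev in events:
        ev.pathway_label = classify_pathway(ev, profile, definitions)
    key_to_label = {_event_key(ev): ev.pathway_label for ev in events}
    if not profile.per_pair.empty:
        profile.per_pair["pathway"] = profile.per_pair["event_key"].map(key_to_label)
    return events


def overlap_and_samepath(events: list[EventRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simultaneous-event counts and same-path exit percentages.

    Overlaps: unordered pairs of events from *different* molecules whose
    traced time spans intersect, tallied by pathway pair (the diagonal holds
    intra-pathway overlaps).  Same-path: per entry pathway, the percentage
    of dwells whose exit carries the same label as the entry.
    """
    labels = sorted({ev.pathway_label or "unassigned" for ev in events})
    overlap = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    evs = sorted(events, key=lambda e: e.span_times[0])
    for i, a in enumerate(evs):
        a0, a1 = a.span_times
        for b in evs[i + 1 :]:
            b0, b1 = b.span_times
            if b0 > a1:
                break
            if a.molecule_id == b.molecule_id:
                continue
            la = a.pathway_label or "unassigned"
            lb = b.pathway_label or "unassigned"
            lo, hi = sorted((la, lb))
            overlap.loc[lo, hi] += 1
            if lo != hi:
                overlap.loc[hi, lo] += 1

    dwells: dict[tuple, dict[str, str]] = {}
    for ev in events:
        dwells.setdefault((ev.molecule_id, ev.dwell_id), {})[ev.direction] = (
            ev.pathway_label or "unassigned"
        )
    rows = []
    per_label: dict[str, list[bool]] = {}
    for pair in dwells.values():
        if "entry" in pair and "exit" in pair:
            per_label.setdefault(pair["entry"], []).append(pair["entry"] == pair["exit"])
    for label in labels:
        matches = per_label.get(label, [])
        rows.append(
            {
                "pathway": label,
                "n_dwells": len(matches),
                "same_path_pct": 100.0 * np.mean(matches) if matches else float("nan"),
            }
        )
    return overlap, pd.DataFrame(rows)
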