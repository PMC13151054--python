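"""Published event tallies for PHD2 flooded-dioxygen simulations.

Literature-reported per-pathway entry/exit counts for the four flooded-O₂
simulation sets of the PHD2·HIF-1α CODD complex (two O₂ force-field
parameterizations, three flooding concentrations).  These serve as worked
inputs for the rate arithmetic helpers: they are *data*, not computed here.

Pathway labels: Pm (main, active-site lumen), Pr (reverse β-sandwich),
P1–P4 (peripheral routes through/around the β2β3 loop and the substrate
peptide).
"""

from __future__ import annotations

import pandas as pd

PATHWAYS = ["Pm", "Pr", "P4", "P3", "P2", "P1"]

# One record per simulation set: O₂ model, number of flooded molecules,
# aggregate simulated time, and per-pathway (entry, exit) counts.
PUBLISHED_EVENT_TALLIES = [
    {
        "system": "O2IF_25", "n_molecules": 25, "total_time_us": 10.0,
        "entries": {"Pm": 26, "Pr": 8, "P4": 7, "P3": 5, "P2": 3, "P1": 3},
        "exits": {"Pm": 23, "Pr": 8, "P4": 4, "P3": 3, "P2": 3, "P1": 1},
        "total_events": 47,
    },
    {
        "system": "O2IF_50", "n_molecules": 50, "total_time_us": 10.0,
        "entries": {"Pm": 27, "Pr": 6, "P4": 4, "P3": 2, "P2": 6, "P1": 5},
        "exits": {"Pm": 31, "Pr": 6, "P4": 5, "P3": 2, "P2": 3, "P1": 3},
        "total_events": 50,
    },
    {
        "system": "O2IF_100", "n_molecules": 100, "total_time_us": 10.0,
        "entries": {"Pm": 66, "Pr": 98, "P4": 55, "P3": 11, "P2": 6, "P1": 13},
        "exits": {"Pm": 66, "Pr": 98, "P4": 54, "P3": 10, "P2": 11, "P1": 10},
        "total_events": 249,
    },
    {
        "system": "O2QD_100", "n_molecules": 100, "total_time_us": 18.0,
        "entries": {"Pm": 158, "Pr": 34, "P4": 59, "P3": 30, "P2": 18, "P1": 9},
        "exits": {"Pm": 147, "Pr": 34, "P4": 47, "P3": 23, "P2": 25, "P1": 8},
        "total_events": 296,
    },
]


def tallies_frame() -> pd.DataFrame:
    """The published tallies as a tidy DataFrame (system × pathway × direction)."""
    rows = []
    for rec in PUBLISHED_EVENT_TALLIES:
        for p in PATHWAYS:
            rows.append({"system": rec["system"], "pathway": p,
                         "direction": "entry", "count": rec["entries"][p]})
            rows.append({"system": rec["system"], "pathway": p,
                         "direction": "exit", "count": rec["exits"][p]})
    return pd.DataFrame(rows)


def pooled_event_total() -> int:
    """Sum of the per-system event totals across all four simulation sets."""
    return sum(rec["total_events"] for rec in PUBLISHED_EVENT_TALLIES)
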