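"""Raft pick-list construction.

Turns per-cell prediction scores into a deterministic list of rafts to
isolate, with per-raft score aggregation, a confident-conflict veto for
multi-cell rafts, confidence bands, and row-major destination-well
assignment across 96-well plates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EXCLUSION_BAND = (0.4, 0.6)  # open interval; boundary scores are eligible

_ROWS = "ABCDEFGH"
_COLS = range(1, 13)


def dest_wells_96() -> list[str]:
    """A1..A12, B1..B12, ..., H12 — row-major 96-well order."""
    return [f"{r}{c}" for r in _ROWS for c in _COLS]


def band_of(score: float, bands: tuple[float, ...] = (0.9, 0.8, 0.7)) -> str:
    """Confidence band label for a score; the strongest band whose
    threshold the score clears on either side, or 'none'."""
    for b in sorted(bands, reverse=True):
        if score >= b or score <= 1.0 - b:
            return f">={b:.1f}"
    return "none"


def build_pick_list(
    cell_scores: pd.DataFrame,
    confidence_threshold: float = 0.8,
    n_max_per_class: int = 96,
    exclusion_band: tuple[float, float] = EXCLUSION_BAND,
    control_rafts: pd.DataFrame | None = None,
    control_every: int = 8,
) -> pd.DataFrame:
    """Build the pick list from scored cells.

    ``cell_scores`` needs columns (cell_id, raft_id, score). Per raft the
    score is the mean of member-cell scores; a raft is vetoed if two
    members conflict confidently (one <= 1 - threshold while another
    >= threshold) or if its mean score falls inside the open exclusion
    band. Survivors are ranked by |score - 0.5| descending (ties broken
    by raft_id) and the top ``n_max_per_class`` per predicted class are
    selected. Destinations are assigned row-major A1..H12 across as many
    96-well plates as needed; optional control rafts (from labeled
    wells) are interleaved every ``control_every``-th slot.

    Returns columns (raft_id, score, n_cells, predicted_class, band,
    dest_plate, dest_well).
    """
    if not 0.5 < confidence_threshold <= 1.0:
        raise ValueError("confidence_threshold must be in (0.5, 1]")
    lo, hi = exclusion_band
    g = cell_scores.groupby("raft_id")["score"]
    agg = g.agg(score="mean", n_cells="size", smin="min", smax="max").reset_index()

    conflict = (agg["smin"] <= 1.0 - confidence_threshold) & (
        agg["smax"] >= confidence_threshold
    )
    excluded = (agg["score"] > lo) & (agg["score"] < hi)
    eligible = agg[~conflict & ~excluded].copy()
    eligible["predicted_class"] = np.where(eligible["score"] > 0.5, "mutant", "WT")
    eligible["rank_key"] = (eligible["score"] - 0.5).abs()
    eligible = eligible.sort_values(
        ["rank_key", "raft_id"], ascending=[False, True], kind="stable"
    )

    picked = (
        eligible.groupby("predicted_class", group_keys=False)
        .head(n_max_per_class)
        .sort_values(["rank_key", "raft_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    picked["band"] = [band_of(s) for s in picked["score"]]
    picked = picked[["raft_id", "score", "n_cells", "predicted_class", "band"]]

    rows = [r._asdict() for r in picked.itertuples(index=False)]
    if control_rafts is not None and len(control_rafts):
        ctrl = control_rafts.sort_values("raft_id").reset_index(drop=True)
        merged: list[dict] = []
        ci = 0
        for i, row in enumerate(rows):
            if control_every and i % control_every == control_every - 1 and ci < len(ctrl):
                c = ctrl.iloc[ci]
                merged.append(
                    {
                        "raft_id": c["raft_id"],
                        "score": float(c.get("score", np.nan)),
                        "n_cells": int(c.get("n_cells", 1)),
                        "predicted_class": "control",
                        "band": "control",
                    }
                )
                ci += 1
            merged.append(row)
        while ci < len(ctrl):
            c = ctrl.iloc[ci]
            merged.append(
                {
                    "raft_id": c["raft_id"],
                    "score": float(c.get("score", np.nan)),
                    "n_cells": int(c.get("n_cells", 1)),
                    "predicted_class": "control",
                    "band": "control",
                }
            )
            ci += 1
        rows = merged

    wells = dest_wells_96()
    for i, row in enumerate(rows):
        row["dest_plate"] = f"D{i // 96 + 1}"
        row["dest_well"] = wells[i % 96]
    out = pd.DataFrame(
        rows,
        columns=["raft_id", "score", "n_cells", "predicted_class", "band", "dest_plate", "dest_well"],
    )
    if out["raft_id"].duplicated().any():
        raise ValueError("duplicate raft_id in pick list")
    return out
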