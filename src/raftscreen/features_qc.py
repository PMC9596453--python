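"""Record-level quality gates, per-plate normalization, leak exclusion.

The fixed pipeline order is: interval/raft gates -> leaky-feature
exclusion -> per-plate robust normalization. Gates reject tracing
artifacts and debris on nuclear morphology and intensity, cells too
close to the raft edge, overcrowded rafts (> max_cells_per_raft) and
fiduciary rafts. Normalization is median/MAD per plate and feature,
robust to residual debris; features with zero MAD on any plate are
flagged constant and excluded from modeling rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# Gate evaluation order = alphabetical by reason code; a rejected record
# is logged with the first failing gate in this order.
GATE_ORDER = (
    "cell_intensity",
    "fiduciary",
    "form_factor",
    "nuclear_area",
    "nuclear_intensity",
    "raft_edge",
    "raft_overcrowded",
)


@dataclass(frozen=True)
class QcGates:
    """Interval gates plus raft-level rules.

    Numeric defaults are intentionally permissive; on synthetic data use
    :meth:`from_reference` to place the intervals at the [1%, 99%]
    quantiles of a reference table of live nuclei.
    """

    nuclear_area: tuple[float, float] = (50.0, 400.0)
    form_factor: tuple[float, float] = (0.6, 1.0)
    nuclear_intensity: tuple[float, float] = (40.0, 1e6)
    cell_intensity: tuple[float, float] = (50.0, 1e7)
    raft_edge_margin: float = 5.0
    max_cells_per_raft: int = 6
    exclude_fiduciary: bool = True

    def __post_init__(self) -> None:
        for name in ("nuclear_area", "form_factor", "nuclear_intensity", "cell_intensity"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"empty gate interval for {name}")
        if self.raft_edge_margin < 0:
            raise ValueError("raft_edge_margin must be nonnegative")

    @classmethod
    def from_reference(
        cls, reference: pd.DataFrame, lower: float = 0.01, upper: float = 0.99, **overrides
    ) -> "QcGates":
        """Gates at quantiles of a reference table of in-gate cells."""
        def q(col: str) -> tuple[float, float]:
            v = reference[col]
            return (float(v.quantile(lower)), float(v.quantile(upper)))

        kw = dict(
            nuclear_area=q("nuc_area"),
            form_factor=q("nuc_form_factor"),
            nuclear_intensity=q("nuc_intensity"),
            cell_intensity=q("cell_intensity"),
        )
        kw.update(overrides)
        return cls(**kw)


_GATE_COLUMNS = {
    "cell_intensity": "cell_intensity",
    "form_factor": "nuc_form_factor",
    "nuclear_area": "nuc_area",
    "nuclear_intensity": "nuc_intensity",
    "raft_edge": "dist_raft_edge",
    "fiduciary": "fiduciary",
}


def apply_qc_gates(cells: pd.DataFrame, gates: QcGates) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter the cell table; return (kept, rejection_log).

    A record is kept iff it passes every gate. The log has one row per
    dropped record, columns (cell_id, reason), reason being the first
    failing gate in :data:`GATE_ORDER`.
    """
    required = set(_GATE_COLUMNS.values()) | {"raft_id", "cell_id"}
    missing = required - set(cells.columns)
    if missing:
        raise KeyError(f"cell table missing gated column(s): {sorted(missing)}")
    if cells.empty:
        return cells.copy(), pd.DataFrame(columns=["cell_id", "reason"])

    raft_counts = cells.groupby("raft_id")["cell_id"].transform("size")
    interval = {
        "cell_intensity": gates.cell_intensity,
        "form_factor": gates.form_factor,
        "nuclear_area": gates.nuclear_area,
        "nuclear_intensity": gates.nuclear_intensity,
    }
    fails: dict[str, np.ndarray] = {}
    for reason, (lo, hi) in interval.items():
        v = cells[_GATE_COLUMNS[reason]].to_numpy(float)
        fails[reason] = ~((v >= lo) & (v <= hi))
    fails["fiduciary"] = (
        cells["fiduciary"].to_numpy(bool) if gates.exclude_fiduciary else np.zeros(len(cells), bool)
    )
    fails["raft_edge"] = cells["dist_raft_edge"].to_numpy(float) < gates.raft_edge_margin
    fails["raft_overcrowded"] = raft_counts.to_numpy() > gates.max_cells_per_raft

    any_fail = np.zeros(len(cells), bool)
    reason = np.full(len(cells), "", object)
    for r in reversed(GATE_ORDER):  # earlier gates overwrite later ones
        any_fail |= fails[r]
        reason[fails[r]] = r
    kept = cells.loc[~any_fail].reset_index(drop=True)
    log = pd.DataFrame(
        {"cell_id": cells.loc[any_fail, "cell_id"].to_numpy(), "reason": reason[any_fail]}
    )
    return kept, log


def normalize_by_plate(
    cells: pd.DataFrame, feature_cols: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per plate and feature: subtract median, divide by sigma-scaled MAD.

    Returns the normalized table and the list of features excluded
    because their MAD is zero on at least one plate (flagged constant).
    Idempotent up to floating-point error.
    """
    out = cells.copy()
    excluded: set[str] = set()
    for plate, idx in cells.groupby("plate").groups.items():
        block = cells.loc[idx, feature_cols].to_numpy(float)
        if block.shape[0] < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 records")
        med = np.median(block, axis=0)
        mad = stats.median_abs_deviation(block, axis=0, scale="normal")
        zero = mad <= 0
        excluded.update(np.asarray(feature_cols)[zero])
        mad[zero] = 1.0
        out.loc[idx, feature_cols] = (block - med) / mad
    return out, sorted(excluded)


def rank_eta_squared(values: np.ndarray, groups: np.ndarray) -> float:
    """Effect size of a one-way rank analysis (Kruskal-Wallis eta^2).

    eta^2_H = (H - k + 1) / (n - k); clipped to [0, 1].
    """
    uniq = pd.unique(groups)
    k = len(uniq)
    n = len(values)
    if k < 2 or n <= k:
        return 0.0
    samples = [values[groups == g] for g in uniq]
    try:
        H, _ = stats.kruskal(*samples)
    except ValueError:  # all values identical
        return 0.0
    return float(np.clip((H - k + 1) / (n - k), 0.0, 1.0))


def flag_leaky_features(
    cells: pd.DataFrame,
    feature_cols: list[str],
    well_col: str = "well",
    plate_col: str = "plate",
    eta2_cutoff: float = 0.5,
    user_blacklist: tuple[str, ...] = (),
) -> list[str]:
    """Blacklist features that proxy well identity.

    A feature is leaky if its rank eta^2 across wells exceeds the cutoff,
    or if it is constant within every well while varying across wells, or
    if the user listed it. With a single well the blacklist is just the
    user list (nothing can be tested).
    """
    black = set(user_blacklist) & set(feature_cols)
    black |= {f for f in user_blacklist if f in cells.columns}
    well_key = (cells[plate_col].astype(str) + ":" + cells[well_col].astype(str)).to_numpy()
    if len(pd.unique(well_key)) < 2:
        return sorted(black)
    for f in feature_cols:
        if f in black:
            continue
        v = cells[f].to_numpy(float)
        per_well_std = pd.Series(v).groupby(well_key).std()
        per_well_mean = pd.Series(v).groupby(well_key).mean()
        if (per_well_std.fillna(0.0) == 0.0).all() and per_well_mean.nunique() > 1:
            black.add(f)
            continue
        if rank_eta_squared(v, well_key) > eta2_cutoff:
            black.add(f)
    return sorted(black)


@dataclass
class QcResult:
    cells: pd.DataFrame
    rejection_log: pd.DataFrame
    constant_features: list[str] = field(default_factory=list)
    leaky_features: list[str] = field(default_factory=list)

    @property
    def usable_features(self) -> list[str]:
        drop = set(self.constant_features) | set(self.leaky_features)
        return [c for c in self.cells.columns if c.startswith("F") and c not in drop]


def run_qc(
    cells: pd.DataFrame,
    gates: QcGates,
    feature_cols: list[str],
    user_blacklist: tuple[str, ...] = (),
    eta2_cutoff: float = 0.5,
) -> QcResult:
    """Full QC pipeline in the fixed order: gates -> leak exclusion ->
    per-plate normalization."""
    kept, log = apply_qc_gates(cells, gates)
    leaky = flag_leaky_features(
        kept, feature_cols, eta2_cutoff=eta2_cutoff, user_blacklist=user_blacklist
    )
    usable = [f for f in feature_cols if f not in set(leaky)]
    normed, constant = normalize_by_plate(kept, usable)
    return QcResult(
        cells=normed, rejection_log=log, constant_features=constant, leaky_features=leaky
    )
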