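"""End-to-end orchestration of the screening pipeline.

Chains simulate -> QC -> model grid -> pick -> amplicon reads ->
genotype -> evaluate with one master seed, entirely in memory. The CLI
wraps these functions with file I/O; tests and the acceptance script
call them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import modeling, picker, synthdata
from .features_qc import QcGates, QcResult, run_qc
from .genotyper import genotype_wells
from .panel import LocusPanel, default_mfn2_panel


@dataclass
class RunResult:
    config: synthdata.SimConfig
    cells: pd.DataFrame
    layout: pd.DataFrame
    truth: synthdata.GroundTruth
    qc: QcResult
    split: modeling.SplitPlan
    model_results: list[modeling.ModelResult]
    pick_model: modeling.ModelResult
    pick_list: pd.DataFrame
    labels: pd.Series
    train_ids: np.ndarray
    test_ids: np.ndarray
    genotype_calls: pd.DataFrame | None = None
    join: pd.DataFrame | None = None
    metrics: dict = field(default_factory=dict)


def labeled_cell_labels(
    cells: pd.DataFrame, layout: pd.DataFrame, truth: synthdata.GroundTruth | None = None
) -> pd.Series:
    """0/1 labels (WT/mutant) for cells in labeled wells, by well role."""
    roles = layout.set_index(layout["plate"] + ":" + layout["well"])["role"]
    key = modeling.well_key(cells)
    role_of = key.map(roles)
    labeled = cells.loc[role_of.isin(["labeled_wt", "labeled_mut"]), "cell_id"]
    lab = (role_of[labeled.index] == "labeled_mut").astype(int)
    return pd.Series(lab.to_numpy(), index=labeled.to_numpy())


def raft_truth_classes(truth: synthdata.GroundTruth) -> pd.Series:
    """raft_id -> majority genotype class of live members (ties dropped)."""
    live = truth.cells[~truth.cells["is_debris"]]
    def majority(s: pd.Series):
        counts = s.value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            return None
        return counts.index[0]
    out = live.groupby("raft_id")["genotype_class"].agg(majority)
    return out.dropna()


def run_modeling(
    config: synthdata.SimConfig,
    seed: int | None = None,
    grid_kwargs: dict | None = None,
) -> RunResult:
    """Simulate one experiment and run it through QC, the model grid,
    pick-model selection and raft picking (no sequencing yet)."""
    seed = config.seed if seed is None else seed
    cells, layout, truth = synthdata.simulate_plate(config)

    live_ids = set(truth.cells.loc[~truth.cells["is_debris"], "cell_id"])
    gates = QcGates.from_reference(cells[cells["cell_id"].isin(live_ids)])
    qc = run_qc(cells, gates, config.feature_names())

    split = modeling.split_wells(layout, mode="well", seed=seed)
    labels = labeled_cell_labels(qc.cells, layout, truth)
    key = modeling.well_key(qc.cells)
    in_train = key.isin(split.train_wells) & qc.cells["cell_id"].isin(labels.index)
    in_test = key.isin(split.test_wells) & qc.cells["cell_id"].isin(labels.index)
    train_ids = qc.cells.loc[in_train, "cell_id"].to_numpy()
    test_ids = qc.cells.loc[in_test, "cell_id"].to_numpy()

    feats = qc.usable_features
    train_X = qc.cells.set_index("cell_id").loc[train_ids, feats]
    train_y = labels.loc[train_ids].to_numpy(int)
    specs = modeling.build_default_grid(train_X, train_y, seed=seed, **(grid_kwargs or {}))
    results = modeling.train_model_grid(
        qc.cells, labels, specs, train_ids, test_ids, layout=layout, seed=seed
    )
    pick_model = modeling.select_pick_model(results)

    # Pick only from unlabeled wells; labeled wells contribute controls.
    roles = layout.set_index(layout["plate"] + ":" + layout["well"])["role"]
    role_of = key.map(roles)
    unlab = qc.cells.loc[role_of.eq("unlabeled_mix").to_numpy(), ["cell_id", "raft_id"]].copy()
    unlab["score"] = unlab["cell_id"].map(pick_model.scores)
    pick_list = picker.build_pick_list(unlab)

    return RunResult(
        config=config,
        cells=cells,
        layout=layout,
        truth=truth,
        qc=qc,
        split=split,
        model_results=results,
        pick_model=pick_model,
        pick_list=pick_list,
        labels=labels,
        train_ids=train_ids,
        test_ids=test_ids,
    )


def run_sequencing(
    run: RunResult,
    panel: LocusPanel | None = None,
    reads_per_cell: int = 30,
    error_rate: float = 0.001,
    capture_rate: float = 0.8,
    seed: int | None = None,
) -> RunResult:
    """Simulate amplicon reads for the picked rafts and genotype them."""
    panel = panel or default_mfn2_panel()
    seed = run.config.seed if seed is None else seed
    reads = synthdata.simulate_amplicon_reads(
        run.pick_list,
        run.truth,
        panel,
        reads_per_cell=reads_per_cell,
        error_rate=error_rate,
        capture_rate=capture_rate,
        seed=seed,
    )
    well_reads = {f"{p}_{w}": v for (p, w), v in reads.items()}
    calls, _counts = genotype_wells(well_reads, panel)
    run.genotype_calls = calls

    class_map = dict(run.config.class_map)
    join = ev.join_predictions_genotypes(run.pick_list, calls, class_map)
    run.join = join
    if len(join) and join["truth"].nunique() == 2:
        _, auc, noise = ev.roc_with_noise(join, seed=seed)
        run.metrics["unlabeled_auc"] = auc
        run.metrics["noise_auc_mean"] = float(noise.mean())
    bands = ev.threshold_metrics(join) if len(join) else None
    if bands is not None:
        run.metrics["band_metrics"] = bands
    pred_mut = join["score"] > 0.5
    run.metrics["pick_accuracy"] = float((pred_mut == (join["truth"] == 1)).mean())
    run.metrics["majority_baseline"] = float(
        max((join["truth"] == 1).mean(), (join["truth"] == 0).mean())
    )
    return run


def truth_join(run: RunResult) -> pd.DataFrame:
    """Join picks to simulation truth directly (no sequencing step).

    Mirrors the evaluation join but uses the majority genotype class of
    each picked raft's live members as truth; ties are dropped.
    """
    classes = raft_truth_classes(run.truth)
    df = run.pick_list.copy()
    df["true_class"] = df["raft_id"].map(classes)
    df = df.dropna(subset=["true_class"]).copy()
    lo, hi = ev.SCORE_EXCLUSION_BAND
    df = df[(df["score"] < lo) | (df["score"] > hi)]
    df["truth"] = (df["true_class"] == "pathogenic").astype(int)
    df["true_genotype"] = df["true_class"]
    return df.reset_index(drop=True)
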