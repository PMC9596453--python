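"""Evaluation battery: predictions vs genotypes, features, gRNA statistics.

Joins the pick-list predictions to the sequencing-derived genotype calls
and reproduces the platform's standard read-outs: overall accuracy and
confusion counts, ROC curves with shuffled-label noise baselines,
accuracy at increasing confidence bands, Kruskal-Wallis feature
rankings, feature-subset / single-feature / leave-one-out model scans,
per-gRNA significance under Benjamini-Hochberg FDR control, replicate
reproducibility, and the frameshift-probability versus anomaly-score
comparison for tiling screens.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

SCORE_EXCLUSION_BAND = (0.4, 0.6)  # closed: scores in [0.4, 0.6] leave metrics


def join_predictions_genotypes(
    pick_list: pd.DataFrame,
    genotype_calls: pd.DataFrame,
    class_map: dict[str, str],
    well_of_raft: dict[str, str] | None = None,
    band: tuple[float, float] = SCORE_EXCLUSION_BAND,
) -> pd.DataFrame:
    """Inner-join picks to genotype calls on the destination well.

    ``genotype_calls`` has columns (well, call); pick rows map to wells
    either via ``well_of_raft`` or as ``<dest_plate>_<dest_well>``.
    Ambiguous and no-data calls are dropped, as are prediction scores
    inside the closed exclusion band. Genotypes missing from
    ``class_map`` raise by name. Output adds true_genotype, true_class
    and a binary truth column (1 = pathogenic).
    """
    picks = pick_list.copy()
    if well_of_raft is not None:
        picks["seq_well"] = picks["raft_id"].map(well_of_raft)
    else:
        picks["seq_well"] = picks["dest_plate"].astype(str) + "_" + picks["dest_well"].astype(str)
    if picks["seq_well"].duplicated().any():
        raise ValueError("join key collision: multiple picks map to one sequencing well")
    calls = genotype_calls.rename(columns={"well": "seq_well"})
    df = picks.merge(calls[["seq_well", "call"]], on="seq_well", how="inner")
    df = df[~df["call"].isin(["ambiguous", "no-data"])].copy()
    lo, hi = band
    df = df[(df["score"] < lo) | (df["score"] > hi)]
    unknown = sorted(set(df["call"]) - set(class_map))
    if unknown:
        raise KeyError(f"genotype(s) missing from class map: {unknown}")
    df["true_genotype"] = df["call"]
    df["true_class"] = df["call"].map(class_map)
    df["truth"] = (df["true_class"] == "pathogenic").astype(int)
    return df.reset_index(drop=True)


def roc_with_noise(
    join: pd.DataFrame, n_shuffles: int = 50, seed: int = 0
) -> tuple[pd.DataFrame, float, np.ndarray]:
    """Empirical ROC plus a shuffled-label noise AUC distribution.

    Returns (roc_points, auc, noise_aucs); roc_points has columns
    (fpr, tpr, threshold).
    """
    y = join["truth"].to_numpy(int)
    s = join["score"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    noise = np.array(
        [roc_auc_score(rng.permutation(y), s) for _ in range(n_shuffles)], dtype=float
    )
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc, noise


def threshold_metrics(
    join: pd.DataFrame, bands: tuple[float, ...] = (0.7, 0.8, 0.9)
) -> pd.DataFrame:
    """Accuracy/AUC/n restricted to increasingly confident scores.

    Per band b, keep scores >= b or <= 1 - b; accuracy is the fraction
    whose predicted class matches the true class (mutant iff
    truth = pathogenic); AUC is reported when both classes remain.
    """
    if join.empty:
        raise ValueError("empty join")
    rows = []
    for b in bands:
        sub = join[(join["score"] >= b) | (join["score"] <= 1.0 - b)]
        if len(sub):
            pred_mut = sub["score"] > 0.5
            acc = float((pred_mut == (sub["truth"] == 1)).mean())
            auc = (
                float(roc_auc_score(sub["truth"], sub["score"]))
                if sub["truth"].nunique() == 2
                else np.nan
            )
        else:
            acc, auc = np.nan, np.nan
        rows.append({"band": b, "n": len(sub), "accuracy": acc, "auc": auc})
    return pd.DataFrame(rows)


def confusion_summary(join: pd.DataFrame, group_keys: list[str] | None = None) -> pd.DataFrame:
    """Stacked (predicted class x true genotype) counts, optionally per
    group; marginals are conserved by construction."""
    df = join.copy()
    df["predicted_class"] = np.where(df["score"] > 0.5, "mutant", "WT")
    keys = (group_keys or []) + ["predicted_class", "true_genotype"]
    out = df.groupby(keys, observed=True).size().rename("n").reset_index()
    return out


def kw_feature_ranking(
    cells: pd.DataFrame, labels: np.ndarray, feature_cols: list[str]
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H per feature between classes,
    ranked descending; columns (feature, kw_chi2, rank)."""
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2 or min((labels == g).sum() for g in groups) < 2:
        raise ValueError("need >= 2 classes with >= 2 cells each")
    rows = []
    for f in feature_cols:
        v = cells[f].to_numpy(float)
        H, _ = stats.kruskal(*[v[labels == g] for g in groups])
        rows.append({"feature": f, "kw_chi2": float(H)})
    out = pd.DataFrame(rows).sort_values("kw_chi2", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def _fit_auc(Xtr, ytr, Xte, yte) -> float:
    clf = LogisticRegression(max_iter=2000)
    clf.fit(Xtr, ytr)
    return float(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))


def feature_subset_analysis(
    train: pd.DataFrame,
    train_labels: np.ndarray,
    test: pd.DataFrame,
    test_labels: np.ndarray,
    base_features: list[str],
    mode: str = "subsets",
    max_combos: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Model scans over a base feature set, AUCs on held-out cells.

    mode='subsets': one logistic model per subset of each size 1..k
    (random sample when a size has more than ``max_combos`` subsets);
    mode='single': one model per feature; mode='leave_one_out': one
    model per excluded feature.
    """
    if len(base_features) < 2:
        raise ValueError("base feature set must have >= 2 features")
    rng = np.random.default_rng(seed)
    rows = []

    def auc_of(feats: list[str]) -> float:
        return _fit_auc(
            train[feats].to_numpy(float), train_labels, test[feats].to_numpy(float), test_labels
        )

    if mode == "single":
        for f in base_features:
            rows.append({"mode": mode, "n_features": 1, "features": f, "auc": auc_of([f])})
    elif mode == "leave_one_out":
        for f in base_features:
            feats = [g for g in base_features if g != f]
            rows.append(
                {"mode": mode, "n_features": len(feats), "features": f"-{f}", "auc": auc_of(feats)}
            )
    elif mode == "subsets":
        k = len(base_features)
        for size in range(1, k + 1):
            combos = list(itertools.combinations(base_features, size))
            if len(combos) > max_combos:
                idx = rng.choice(len(combos), size=max_combos, replace=False)
                combos = [combos[i] for i in idx]
            for feats in combos:
                rows.append(
                    {
                        "mode": mode,
                        "n_features": size,
                        "features": ",".join(feats),
                        "auc": auc_of(list(feats)),
                    }
                )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def grna_significance(
    cell_scores: pd.DataFrame,
    null_value: float | None = None,
    fdr: float = 0.2,
    min_cells: int = 3,
    control_grnas: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-gRNA one-sample t test with Benjamini-Hochberg control.

    ``cell_scores`` needs columns (grna_id, score). The null value
    defaults to the median score of ``control_grnas`` cells (or of all
    cells if none are given). gRNAs with fewer than ``min_cells`` cells
    are excluded. Returns (grna_id, n_cells, mean_score, t_stat, p_value,
    significant).
    """
    if null_value is None:
        if control_grnas:
            ctrl = cell_scores[cell_scores["grna_id"].isin(control_grnas)]["score"]
        else:
            ctrl = cell_scores["score"]
        null_value = float(ctrl.median())
    rows = []
    for grna, sub in cell_scores.groupby("grna_id"):
        s = sub["score"].to_numpy(float)
        if len(s) < min_cells:
            continue
        if np.allclose(s, null_value):
            t, p = 0.0, 1.0
        elif np.std(s, ddof=1) == 0:
            t, p = np.inf * np.sign(s.mean() - null_value), 0.0
        else:
            t, p = stats.ttest_1samp(s, null_value)
        rows.append(
            {
                "grna_id": grna,
                "n_cells": len(s),
                "mean_score": float(s.mean()),
                "t_stat": float(t),
                "p_value": float(p),
            }
        )
    cols = ["grna_id", "n_cells", "mean_score", "t_stat", "p_value"]
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        reject, *_ = multipletests(out["p_value"], alpha=fdr, method="fdr_bh")
        out["significant"] = reject
    else:
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["null_value"] = null_value
    return out


def bh_stepup(p_values: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections (boolean mask).

    Reject hypotheses (1)..(j*) where j* = max{ j : p_(j) <= j q / m }.
    Thin wrapper kept as the package's explicit statement of the rule.
    """
    reject, *_ = multipletests(np.asarray(p_values, float), alpha=q, method="fdr_bh")
    return reject


def reproducibility(
    cell_scores: pd.DataFrame, min_cells: int = 3
) -> tuple[float, pd.DataFrame]:
    """Replicate reproducibility of per-gRNA direction.

    ``cell_scores`` needs columns (grna_id, replicate, score). A gRNA is
    measurable iff it has >= ``min_cells`` cells in >= 2 replicates; it
    is reproducible iff the sign of (replicate mean score - that
    replicate's overall median score) agrees across all its measurable
    replicates. Returns (fraction reproducible over measurable gRNAs,
    per-gRNA table).
    """
    rep_median = cell_scores.groupby("replicate")["score"].median()
    g = cell_scores.groupby(["grna_id", "replicate"])["score"].agg(["mean", "size"]).reset_index()
    g = g[g["size"] >= min_cells]
    g["direction"] = np.sign(g["mean"] - g["replicate"].map(rep_median))
    rows = []
    for grna, sub in g.groupby("grna_id"):
        measurable = len(sub) >= 2
        reproducible = bool(measurable and sub["direction"].nunique() == 1)
        rows.append(
            {"grna_id": grna, "n_replicates": len(sub), "measurable": measurable, "reproducible": reproducible}
        )
    table = pd.DataFrame(rows)
    meas = table[table["measurable"]]
    frac = float(meas["reproducible"].mean()) if len(meas) else float("nan")
    return frac, table


def frameshift_vs_anomaly(
    grna_table: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.9, 0.8, 0.7),
) -> pd.DataFrame:
    """Rank-sum comparison of anomaly scores at frameshift thresholds.

    ``grna_table`` needs columns (grna_id, anomaly_score,
    frameshift_prob). At each threshold t, anomaly scores of gRNAs with
    frameshift probability >= t are compared to those < t by a
    two-sided Mann-Whitney test. Empty groups are reported
    not-computable (NaN statistic/p).
    """
    rows = []
    for t in thresholds:
        hi = grna_table.loc[grna_table["frameshift_prob"] >= t, "anomaly_score"]
        lo = grna_table.loc[grna_table["frameshift_prob"] < t, "anomaly_score"]
        if len(hi) == 0 or len(lo) == 0:
            rows.append(
                {"threshold": t, "n_above": len(hi), "n_below": len(lo), "statistic": np.nan, "p_value": np.nan}
            )
            continue
        stat, p = stats.mannwhitneyu(hi, lo, alternative="two-sided")
        rows.append(
            {
                "threshold": t,
                "n_above": len(hi),
                "n_below": len(lo),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
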