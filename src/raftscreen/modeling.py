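"""Supervised classifier ensemble: build, evaluate, select the pick model.

Models are binary classifiers (logistic regression, ridge classifier,
linear SVM) trained on labeled wells to separate wild-type from pooled
mutant cells. Many models are generated over a grid of algorithms,
regularization strengths and feature subsets; each is evaluated on
held-out labeled wells (AUC, MCC) and against the mixture-proportion
meta-feature of the unlabeled wells (the expected WT:mutant ratio is
known even though individual genotypes are not). The pick model is the
best test-AUC model after penalizing train-test gap, meta deviation and
model size, with a deterministic hash tie-break.

Score contract: every model emits scores in [0, 1]; 0 = confident WT,
1 = confident mutant. Margin classifiers are squashed through a logistic
so the contract holds for all three algorithm families.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.metrics import matthews_corrcoef, roc_auc_score
from sklearn.svm import LinearSVC

ALGORITHMS = ("logistic", "ridge", "linear_svm")

# Meta-feature / picking exclusion band: scores here mean "model cannot
# classify this cell" and are dropped from proportion estimates.
EXCLUSION_BAND = (0.4, 0.6)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    mode: str  # "well" | "random"
    train_wells: tuple[str, ...] = ()
    test_wells: tuple[str, ...] = ()
    train_cells: tuple[str, ...] = ()
    test_cells: tuple[str, ...] = ()


def split_wells(
    layout: pd.DataFrame,
    mode: str = "well",
    seed: int = 0,
    cells: pd.DataFrame | None = None,
    test_fraction: float = 0.2,
    train_wells_per_class: int = 2,
) -> SplitPlan:
    """Build the train/test split.

    Well-wise mode: per labeled class, ``train_wells_per_class`` wells go
    to training — placed on distinct plates when possible — and the rest
    to testing; a well is never split. Random mode: cells (required) are
    shuffled into an 80-20 split by seed.
    """
    rng = np.random.default_rng(seed)
    if mode == "random":
        if cells is None:
            raise ValueError("random mode needs the cell table")
        ids = cells["cell_id"].to_numpy()
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        test = ids[perm[:n_test]]
        train = ids[perm[n_test:]]
        return SplitPlan(mode="random", train_cells=tuple(train), test_cells=tuple(test))
    if mode != "well":
        raise ValueError(f"unknown split mode {mode!r}")

    train_wells: list[str] = []
    test_wells: list[str] = []
    for role in ("labeled_wt", "labeled_mut"):
        sub = layout[layout["role"] == role]
        if len(sub) < 2:
            raise ValueError(f"well-wise split needs >= 2 labeled wells for {role}")
        keys = (sub["plate"] + ":" + sub["well"]).tolist()
        plates = sub["plate"].tolist()
        order = rng.permutation(len(keys))
        chosen: list[int] = []
        for i in order:  # greedy: prefer wells on plates not yet used
            if len(chosen) >= train_wells_per_class:
                break
            if plates[i] not in {plates[j] for j in chosen}:
                chosen.append(i)
        for i in order:
            if len(chosen) >= train_wells_per_class:
                break
            if i not in chosen:
                chosen.append(i)
        train_wells += [keys[i] for i in chosen]
        test_wells += [k for j, k in enumerate(keys) if j not in chosen]
    return SplitPlan(mode="well", train_wells=tuple(train_wells), test_wells=tuple(test_wells))


def well_key(cells: pd.DataFrame) -> pd.Series:
    return cells["plate"].astype(str) + ":" + cells["well"].astype(str)


# ---------------------------------------------------------------------------
# Synthetic minority oversampling
# ---------------------------------------------------------------------------

def oversample_minority(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
    return_parents: bool = False,
):
    """Balance classes by SMOTE-style convex interpolation.

    Synthetic minority points are built as ``p + u * (q - p)`` with
    ``u ~ Uniform(0, 1)``, ``p`` a random minority point and ``q`` one of
    its k nearest minority neighbors, until class counts are equal.
    Already-balanced input is returned unchanged. A singleton minority
    class is duplicated verbatim (degenerate fallback).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("oversampling requires exactly two classes")
    if counts[0] == counts[1]:
        if return_parents:
            return X, y, []
        return X, y
    minority = classes[np.argmin(counts)]
    Xm = X[y == minority]
    n_new = int(abs(counts[0] - counts[1]))
    rng = np.random.default_rng(seed)

    if len(Xm) == 1:
        synth = np.repeat(Xm, n_new, axis=0)
        parents = [(0, 0, 0.0)] * n_new
    else:
        k = min(k_neighbors, len(Xm) - 1)
        d = np.linalg.norm(Xm[:, None, :] - Xm[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k]
        pi = rng.integers(0, len(Xm), n_new)
        qi = nn[pi, rng.integers(0, k, n_new)]
        u = rng.random(n_new)
        synth = Xm[pi] + u[:, None] * (Xm[qi] - Xm[pi])
        parents = list(zip(pi.tolist(), qi.tolist(), u.tolist()))

    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    if return_parents:
        return X_out, y_out, parents
    return X_out, y_out


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------

def select_features(
    X: pd.DataFrame,
    y: np.ndarray | None,
    method: str,
    seed: int = 0,
    size: int = 8,
    min_variance: float = 1e-8,
    max_correlation: float = 0.95,
    l1_C: float = 0.1,
) -> list[str]:
    """Pick a feature subset by one of five methods.

    variance: drop features below ``min_variance``. correlation: greedily
    drop one member of each pair with \\|r\\| > ``max_correlation`` (keep
    the higher-variance member). random: uniform subset of ``size``.
    anova_f: top ``size`` by one-way F between classes. l1svm: features
    with nonzero coefficients of an L1 linear SVM at penalty ``l1_C``.
    """
    cols = list(X.columns)
    if method == "variance":
        var = X.var(axis=0, ddof=1)
        return [c for c in cols if var[c] >= min_variance]
    if method == "correlation":
        var = X.var(axis=0, ddof=1)
        corr = np.corrcoef(X.to_numpy(float), rowvar=False)
        keep = list(cols)
        dropped: set[str] = set()
        for i, j in itertools.combinations(range(len(cols)), 2):
            a, b = cols[i], cols[j]
            if a in dropped or b in dropped:
                continue
            if abs(corr[i, j]) > max_correlation:
                dropped.add(a if var[a] < var[b] else b)
        return [c for c in keep if c not in dropped]
    if method == "random":
        if size > len(cols):
            raise ValueError("requested subset larger than available features")
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(cols), size=size, replace=False))
        return [cols[i] for i in idx]
    if y is None:
        raise ValueError(f"method {method!r} needs class labels")
    if method == "anova_f":
        if size > len(cols):
            raise ValueError("requested subset larger than available features")
        F, _ = f_classif(X.to_numpy(float), y)
        F = np.nan_to_num(F, nan=-np.inf)
        top = np.argsort(-F, kind="stable")[:size]
        return [cols[i] for i in sorted(top)]
    if method == "l1svm":
        clf = LinearSVC(penalty="l1", dual=False, C=l1_C, max_iter=5000)
        clf.fit(X.to_numpy(float), y)
        nz = np.flatnonzero(np.abs(clf.coef_.ravel()) > 1e-9)
        return [cols[i] for i in nz]
    raise ValueError(f"unknown feature-selection method {method!r}")


# ---------------------------------------------------------------------------
# Model grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    regularization: float  # inverse-strength C for logistic/SVM, alpha for ridge
    feature_subset: tuple[str, ...]
    selection_method: str = "manual"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not self.feature_subset:
            raise ValueError("feature_subset must be non-empty")

    @property
    def model_id(self) -> str:
        return self.spec_hash()[:12]

    def spec_hash(self) -> str:
        payload = f"{self.algorithm}|{self.regularization}|{','.join(self.feature_subset)}|{self.seed}"
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class ModelResult:
    spec: ModelSpec
    estimator: object | None = None
    auc_train: float = np.nan
    auc_test: float = np.nan
    mcc_test: float = np.nan
    meta_deviation: float = np.nan
    scores: pd.Series | None = None  # per-cell score, index = cell_id
    failed: bool = False
    note: str = ""


def _make_estimator(spec: ModelSpec):
    if spec.algorithm == "logistic":
        return LogisticRegression(C=spec.regularization, max_iter=2000)
    if spec.algorithm == "ridge":
        return RidgeClassifier(alpha=spec.regularization)
    return LinearSVC(C=spec.regularization, max_iter=5000)


def _score_cells(est, X: np.ndarray) -> np.ndarray:
    """Map estimator output to the [0, 1] score contract."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    margin = est.decision_function(X)
    return expit(margin)


def build_default_grid(
    train_X: pd.DataFrame,
    train_y: np.ndarray,
    regularizations: tuple[float, ...] = (0.1, 1.0, 10.0),
    n_random_subsets: int = 8,
    random_sizes: tuple[int, ...] = (2, 4, 8, 16),
    anova_sizes: tuple[int, ...] = (4, 8, 16),
    seed: int = 0,
) -> list[ModelSpec]:
    """Default grid: 3 algorithms x 3 regularization strengths x feature
    subsets drawn from the five selection methods (a few hundred specs)."""
    rng = np.random.default_rng(seed)
    subsets: list[tuple[str, tuple[str, ...]]] = []
    for method in ("variance", "correlation"):
        cols = select_features(train_X, train_y, method)
        if cols:
            subsets.append((method, tuple(cols)))
    for sz in anova_sizes:
        cols = select_features(train_X, train_y, "anova_f", size=min(sz, train_X.shape[1]))
        subsets.append(("anova_f", tuple(cols)))
    cols = select_features(train_X, train_y, "l1svm")
    if cols:
        subsets.append(("l1svm", tuple(cols)))
    for sz in random_sizes:
        for _ in range(n_random_subsets // len(random_sizes) + 1):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            cols = select_features(
                train_X, None, "random", seed=sub_seed, size=min(sz, train_X.shape[1])
            )
            subsets.append(("random", tuple(cols)))
    specs = []
    for algo in ALGORITHMS:
        for reg in regularizations:
            for method, sub in subsets:
                specs.append(
                    ModelSpec(
                        algorithm=algo,
                        regularization=reg,
                        feature_subset=sub,
                        selection_method=method,
                    )
                )
    return specs


def evaluate_model(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(AUC, MCC at threshold 0.5); AUC is the rank/trapezoid statistic
    with ties credited 0.5. Raises on a single-class label set."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined on a single-class test set")
    auc = roc_auc_score(labels, scores)
    mcc = matthews_corrcoef(labels, (np.asarray(scores) > 0.5).astype(int))
    return float(auc), float(mcc)


def meta_feature_check(
    scores: pd.Series,
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    band: tuple[float, float] = EXCLUSION_BAND,
) -> tuple[float, pd.DataFrame]:
    """Mixture-proportion validation on unlabeled wells.

    Per unlabeled well the predicted positive fraction is the fraction of
    cells scoring > 0.5 after excluding scores inside the band
    [0.4, 0.6]; the meta deviation is the mean absolute difference from
    the expected positive fraction over unlabeled wells. A well whose
    scores are all excluded contributes the worst-case deviation 1.0.

    Returns (meta_deviation, per-well table). With no unlabeled wells the
    deviation is NaN.
    """
    lo, hi = band
    unlab = layout[layout["role"] == "unlabeled_mix"]
    rows = []
    key = well_key(cells)
    smap = cells["cell_id"].map(scores)
    for row in unlab.itertuples(index=False):
        mask = (key == f"{row.plate}:{row.well}").to_numpy()
        s = smap.to_numpy(float)[mask]
        s = s[~np.isnan(s)]
        eligible = s[(s < lo) | (s > hi)]
        if len(eligible) == 0:
            pred_frac, dev = np.nan, 1.0
        else:
            pred_frac = float((eligible > 0.5).mean())
            dev = abs(pred_frac - row.positive_fraction)
        rows.append(
            {
                "plate": row.plate,
                "well": row.well,
                "expected_fraction": row.positive_fraction,
                "predicted_fraction": pred_frac,
                "n_eligible": len(eligible),
                "deviation": dev,
            }
        )
    table = pd.DataFrame(rows)
    meta = float(table["deviation"].mean()) if len(table) else float("nan")
    return meta, table


def train_model_grid(
    cells: pd.DataFrame,
    labels: pd.Series,
    specs: list[ModelSpec],
    train_ids: np.ndarray,
    test_ids: np.ndarray,
    layout: pd.DataFrame | None = None,
    oversample: bool = True,
    seed: int = 0,
) -> list[ModelResult]:
    """Fit every spec; score all cells; evaluate on the held-out set.

    ``labels`` is a cell_id-indexed Series of {0 WT, 1 mutant} over the
    labeled cells; unlabeled cells are scored but never used for fitting.
    Singular/failed fits are flagged and excluded from selection.
    """
    cells = cells.set_index("cell_id", drop=False)
    results: list[ModelResult] = []
    y_train = labels.loc[train_ids].to_numpy(int)
    y_test = labels.loc[test_ids].to_numpy(int)
    for spec in specs:
        feats = list(spec.feature_subset)
        try:
            Xtr = cells.loc[train_ids, feats].to_numpy(float)
            if oversample and len(np.unique(y_train)) == 2:
                Xb, yb = oversample_minority(Xtr, y_train, seed=seed)
            else:
                Xb, yb = Xtr, y_train
            est = _make_estimator(spec)
            est.fit(Xb, yb)
            all_scores = pd.Series(
                _score_cells(est, cells[feats].to_numpy(float)), index=cells.index
            )
            auc_tr, _ = evaluate_model(all_scores.loc[train_ids].to_numpy(), y_train)
            auc_te, mcc_te = evaluate_model(all_scores.loc[test_ids].to_numpy(), y_test)
            res = ModelResult(
                spec=spec,
                estimator=est,
                auc_train=auc_tr,
                auc_test=auc_te,
                mcc_test=mcc_te,
                scores=all_scores,
            )
            if layout is not None:
                res.meta_deviation, _ = meta_feature_check(all_scores, cells, layout)
        except Exception as exc:  # singular fit, degenerate subset, ...
            res = ModelResult(spec=spec, failed=True, note=str(exc))
        results.append(res)
    return results


def select_pick_model(results: list[ModelResult], delta_auc: float = 0.02) -> ModelResult:
    """Deterministic pick-model rule.

    Among non-failed models within ``delta_auc`` of the best test AUC,
    prefer the smallest train-test AUC gap, then smallest meta deviation,
    then fewest features, then lowest spec hash.
    """
    ok = [r for r in results if not r.failed and np.isfinite(r.auc_test)]
    if not ok:
        raise ValueError("no successfully trained models to select from")
    best = max(r.auc_test for r in ok)
    pool = [r for r in ok if r.auc_test >= best - delta_auc]

    def key(r: ModelResult):
        meta = r.meta_deviation if np.isfinite(r.meta_deviation) else 1.0
        return (r.auc_train - r.auc_test, meta, len(r.spec.feature_subset), r.spec.spec_hash())

    return min(pool, key=key)


def ensemble_predict(results: list[ModelResult]) -> pd.Series:
    """Per-cell mean score over >= 2 member models."""
    members = [r for r in results if r.scores is not None]
    if len(members) < 2:
        raise ValueError("ensemble needs at least 2 scored models")
    return pd.concat([r.scores for r in members], axis=1).mean(axis=1)


def results_table(results: list[ModelResult]) -> pd.DataFrame:
    """One row per model: spec fields and metrics (export contract)."""
    return pd.DataFrame(
        [
            {
                "model_id": r.spec.model_id,
                "algorithm": r.spec.algorithm,
                "regularization": r.spec.regularization,
                "selection_method": r.spec.selection_method,
                "n_features": len(r.spec.feature_subset),
                "features": ",".join(r.spec.feature_subset),
                "auc_train": r.auc_train,
                "auc_test": r.auc_test,
                "mcc_test": r.mcc_test,
                "meta_deviation": r.meta_deviation,
                "failed": r.failed,
            }
            for r in results
        ]
    )
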