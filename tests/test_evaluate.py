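"""Evaluation battery: joins, ROC, thresholds, KW, BH, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from raftscreen import evaluate as ev


def bh_bruteforce(pvals, q):
    """Exhaustive step-up oracle: find the largest j with p_(j) <= j q / m
    and reject everything at or below it."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    sorted_p = np.asarray(pvals)[order]
    jstar = 0
    for j in range(1, m + 1):
        if sorted_p[j - 1] <= j * q / m:
            jstar = j
    reject = np.zeros(m, bool)
    reject[order[:jstar]] = True
    return reject


def _join(scores, truths, genotypes=None):
    n = len(scores)
    genotypes = genotypes or ["L76P" if t else "WT" for t in truths]
    return pd.DataFrame(
        {
            "score": scores,
            "truth": truths,
            "true_genotype": genotypes,
            "true_class": ["pathogenic" if t else "WT" for t in truths],
        }
    )


class TestJoin:
    def _picks(self, n):
        return pd.DataFrame(
            {
                "raft_id": [f"R{i}" for i in range(n)],
                "score": np.linspace(0.05, 0.95, n),
                "dest_plate": "D1",
                "dest_well": [f"A{i}" for i in range(n)],
            }
        )

    def test_ambiguous_and_no_data_excluded(self):
        picks = self._picks(10)
        calls = pd.DataFrame(
            {
                "well": [f"D1_A{i}" for i in range(10)],
                "call": ["WT"] * 4 + ["L76P"] * 4 + ["ambiguous", "no-data"],
            }
        )
        cmap = {"WT": "WT", "L76P": "pathogenic"}
        out = ev.join_predictions_genotypes(picks, calls, cmap)
        # 8 clean calls, minus any with scores inside [0.4, 0.6]
        assert set(out["call"]) <= {"WT", "L76P"}
        assert len(out) == 8 - ((picks["score"][:8] >= 0.4) & (picks["score"][:8] <= 0.6)).sum()

    def test_band_scores_excluded(self):
        picks = self._picks(3)
        picks["score"] = [0.5, 0.9, 0.1]
        calls = pd.DataFrame({"well": ["D1_A0", "D1_A1", "D1_A2"], "call": ["WT"] * 3})
        out = ev.join_predictions_genotypes(picks, calls, {"WT": "WT"})
        assert len(out) == 2

    def test_unknown_genotype_named_in_error(self):
        picks = self._picks(1)
        picks["score"] = [0.9]
        calls = pd.DataFrame({"well": ["D1_A0"], "call": ["V999X"]})
        with pytest.raises(KeyError, match="V999X"):
            ev.join_predictions_genotypes(picks, calls, {"WT": "WT"})


class TestRocWithNoise:
    def test_perfect_join_and_null_noise(self):
        j = _join([0.9] * 20 + [0.1] * 20, [1] * 20 + [0] * 20)
        points, auc, noise = ev.roc_with_noise(j, n_shuffles=100, seed=0)
        assert auc == 1.0
        assert abs(noise.mean() - 0.5) < 0.05

    def test_auc_matches_concordance_oracle(self):
        from tests.conftest import pairwise_concordance_auc

        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = np.round(rng.random(60), 2)
            truth = rng.integers(0, 2, 60)
            if truth.min() == truth.max():
                continue
            j = _join(scores, truth)
            _, auc, _ = ev.roc_with_noise(j, n_shuffles=1, seed=0)
            assert abs(auc - pairwise_concordance_auc(scores, truth)) < 1e-12

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        truth = rng.integers(0, 2, 50)
        _, auc, _ = ev.roc_with_noise(_join(scores, truth), n_shuffles=1, seed=0)
        _, auc_inv, _ = ev.roc_with_noise(_join(scores, 1 - truth), n_shuffles=1, seed=0)
        assert abs(auc_inv - (1 - auc)) < 1e-12

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            ev.roc_with_noise(_join([0.9, 0.8], [1, 1]))


class TestThresholdMetrics:
    def test_all_confident_all_correct(self):
        j = _join([0.95] * 5 + [0.05] * 5, [1] * 5 + [0] * 5)
        out = ev.threshold_metrics(j)
        assert (out["accuracy"] == 1.0).all()
        assert list(out["n"]) == [10, 10, 10]

    def test_band_restriction_counts(self):
        j = _join([0.95, 0.85], [1, 0])  # 0.85 wrong but outside 0.9 band
        out = ev.threshold_metrics(j, bands=(0.9,))
        assert out["n"].iloc[0] == 1
        assert out["accuracy"].iloc[0] == 1.0

    def test_empty_join_raises(self):
        with pytest.raises(ValueError):
            ev.threshold_metrics(_join([], []))


class TestConfusion:
    def test_marginals_conserved(self):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        truth = rng.integers(0, 2, 100)
        j = _join(scores, truth)
        out = ev.confusion_summary(j)
        assert out["n"].sum() == 100
        # accuracy recomputable from confusion counts
        pred_mut = out[out["predicted_class"] == "mutant"]
        acc_from_conf = (
            out[(out["predicted_class"] == "mutant") & (out["true_genotype"] == "L76P")]["n"].sum()
            + out[(out["predicted_class"] == "WT") & (out["true_genotype"] == "WT")]["n"].sum()
        ) / 100
        direct = ((scores > 0.5) == (truth == 1)).mean()
        assert np.isclose(acc_from_conf, direct)


class TestKruskalWallis:
    def test_hand_computed_example(self):
        """H({1,2,3},{4,5,6}) = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 3.857."""
        df = pd.DataFrame({"F1": [1, 2, 3, 4, 5, 6]})
        labels = np.array([0, 0, 0, 1, 1, 1])
        out = ev.kw_feature_ranking(df, labels, ["F1"])
        assert abs(out["kw_chi2"].iloc[0] - 3.857) < 0.001

    def test_null_distribution_rarely_extreme(self):
        crit = stats.chi2.ppf(0.99, df=1)
        exceed = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"F1": rng.normal(size=200)})
            labels = rng.integers(0, 2, 200)
            out = ev.kw_feature_ranking(df, labels, ["F1"])
            exceed += out["kw_chi2"].iloc[0] > crit
        assert exceed <= 3

    def test_informative_feature_ranked_first(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            labels = rng.integers(0, 2, 300)
            df = pd.DataFrame(rng.normal(size=(300, 5)), columns=[f"F{i}" for i in range(5)])
            df["F0"] += 2.0 * labels
            out = ev.kw_feature_ranking(df, labels, list(df.columns))
            wins += out["feature"].iloc[0] == "F0"
        assert wins >= 19

    def test_requires_two_populated_classes(self):
        df = pd.DataFrame({"F1": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            ev.kw_feature_ranking(df, np.array([0, 0, 0]), ["F1"])


class TestFeatureSubsetAnalysis:
    def _data(self, seed=0, n=240, p=8):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"F{i}" for i in range(p)])
        y = rng.integers(0, 2, n)
        X["F0"] += 1.5 * y
        return X.iloc[: n // 2], y[: n // 2], X.iloc[n // 2 :], y[n // 2 :]

    def test_single_mode_emits_one_auc_per_feature(self):
        tr, ytr, te, yte = self._data()
        out = ev.feature_subset_analysis(tr, ytr, te, yte, list(tr.columns), mode="single")
        assert len(out) == 8
        assert (out["n_features"] == 1).all()

    def test_leave_one_out_count(self):
        tr, ytr, te, yte = self._data()
        out = ev.feature_subset_analysis(tr, ytr, te, yte, list(tr.columns), mode="leave_one_out")
        assert len(out) == 8
        assert (out["n_features"] == 7).all()

    def test_mean_auc_nondecreasing_in_subset_size(self):
        tr, ytr, te, yte = self._data(seed=5)
        out = ev.feature_subset_analysis(
            tr, ytr, te, yte, list(tr.columns)[:5], mode="subsets", seed=1
        )
        means = out.groupby("n_features")["auc"].mean()
        # informative feature joins more subsets as size grows
        assert means.iloc[-1] >= means.iloc[0]


class TestGrnaStats:
    def test_bh_stepup_hand_example(self):
        # p = {0.01, 0.02, 0.03, 0.5}, q = 0.2, m = 4:
        # thresholds 0.05, 0.10, 0.15, 0.20 -> first three rejected
        reject = ev.bh_stepup(np.array([0.01, 0.02, 0.03, 0.5]), q=0.2)
        assert list(reject) == [True, True, True, False]

    def test_bh_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            m = int(rng.integers(1, 50))
            p = rng.random(m)
            q = float(rng.choice([0.05, 0.1, 0.2]))
            assert np.array_equal(ev.bh_stepup(p, q), bh_bruteforce(p, q))

    def test_scores_at_null_not_significant(self):
        df = pd.DataFrame({"grna_id": ["g1"] * 5 + ["g2"] * 5, "score": 0.5})
        out = ev.grna_significance(df, null_value=0.5)
        assert not out["significant"].any()
        assert (out["t_stat"] == 0.0).all()

    def test_shifted_grna_detected(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in range(20):
            shift = 0.4 if g == 0 else 0.0
            for s in rng.normal(0.5 + shift, 0.05, 8):
                rows.append({"grna_id": f"g{g:02d}", "score": s})
        out = ev.grna_significance(pd.DataFrame(rows), null_value=0.5, fdr=0.2)
        assert out.loc[out["grna_id"] == "g00", "significant"].iloc[0]

    def test_small_grnas_excluded(self):
        df = pd.DataFrame({"grna_id": ["g1", "g1", "g2"], "score": [0.9, 0.8, 0.1]})
        out = ev.grna_significance(df, null_value=0.5, min_cells=3)
        assert "g2" not in set(out["grna_id"])


class TestReproducibility:
    def _scores(self, spec):
        rows = []
        for grna, reps in spec.items():
            for rep, vals in reps.items():
                for v in vals:
                    rows.append({"grna_id": grna, "replicate": rep, "score": v})
        return pd.DataFrame(rows)

    def test_consistent_direction_reproducible(self):
        df = self._scores(
            {
                "hi": {"r1": [0.9] * 3, "r2": [0.8] * 3},
                "lo": {"r1": [0.1] * 3, "r2": [0.2] * 3},
            }
        )
        frac, table = ev.reproducibility(df)
        assert frac == 1.0

    def test_flipped_direction_not_reproducible(self):
        df = self._scores(
            {
                "flip": {"r1": [0.9] * 3, "r2": [0.1] * 3},
                "hi": {"r1": [0.95] * 3, "r2": [0.9] * 3},
                "lo": {"r1": [0.05] * 3, "r2": [0.1] * 3},
            }
        )
        frac, table = ev.reproducibility(df)
        flip = table[table["grna_id"] == "flip"]
        assert not flip["reproducible"].iloc[0]

    def test_single_replicate_not_measurable(self):
        df = self._scores(
            {
                "only_r1": {"r1": [0.9] * 4},
                "hi": {"r1": [0.95] * 3, "r2": [0.9] * 3},
                "lo": {"r1": [0.05] * 3, "r2": [0.1] * 3},
            }
        )
        frac, table = ev.reproducibility(df)
        row = table[table["grna_id"] == "only_r1"]
        assert not row["measurable"].iloc[0]
        assert frac == 1.0  # denominator excludes the unmeasurable gRNA


class TestFrameshiftVsAnomaly:
    def test_constructed_association_significant(self):
        rng = np.random.default_rng(8)
        fs = rng.random(300)
        table = pd.DataFrame(
            {
                "grna_id": [f"g{i}" for i in range(300)],
                "frameshift_prob": fs,
                "anomaly_score": fs + rng.normal(0, 0.01, 300),
            }
        )
        out = ev.frameshift_vs_anomaly(table)
        assert (out["p_value"] < 0.01).all()

    def test_null_p_uniformish(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "grna_id": [f"g{i}" for i in range(80)],
                    "frameshift_prob": rng.random(80),
                    "anomaly_score": rng.random(80),
                }
            )
            out = ev.frameshift_vs_anomaly(table, thresholds=(0.8,))
            ps.append(out["p_value"].iloc[0])
        assert 0.35 <= np.mean(ps) <= 0.65

    def test_empty_group_not_computable(self):
        table = pd.DataFrame(
            {"grna_id": ["g1", "g2"], "frameshift_prob": [0.1, 0.2], "anomaly_score": [1, 2]}
        )
        out = ev.frameshift_vs_anomaly(table, thresholds=(0.9,))
        assert np.isnan(out["p_value"].iloc[0])
        assert out["n_above"].iloc[0] == 0
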