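"""Classifier grid: splits, oversampling, selection, evaluation, picking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from raftscreen import modeling, synthdata, workflow
from tests.conftest import pairwise_concordance_auc, two_class_scores


class TestSplitWells:
    def _layout(self):
        return synthdata.build_layout(synthdata.SimConfig())

    def test_well_wise_train_spans_plates(self):
        layout = self._layout()
        plan = modeling.split_wells(layout, mode="well", seed=1)
        for role in ("labeled_wt", "labeled_mut"):
            wells = set(
                layout.loc[layout["role"] == role, "plate"]
                + ":"
                + layout.loc[layout["role"] == role, "well"]
            )
            train = [w for w in plan.train_wells if w in wells]
            assert len(train) == 2
            assert len({w.split(":")[0] for w in train}) == 2  # distinct plates

    def test_well_never_split(self):
        plan = modeling.split_wells(self._layout(), mode="well", seed=2)
        assert not set(plan.train_wells) & set(plan.test_wells)

    def test_random_80_20(self):
        cells = pd.DataFrame({"cell_id": [f"c{i}" for i in range(100)]})
        plan = modeling.split_wells(self._layout(), mode="random", seed=3, cells=cells)
        assert len(plan.train_cells) == 80
        assert len(plan.test_cells) == 20
        assert not set(plan.train_cells) & set(plan.test_cells)

    def test_same_seed_same_split(self):
        a = modeling.split_wells(self._layout(), seed=7)
        b = modeling.split_wells(self._layout(), seed=7)
        assert a == b

    def test_single_labeled_well_rejected(self):
        layout = self._layout()
        layout = layout[~((layout["role"] == "labeled_wt") & (layout.index > 0))]
        with pytest.raises(ValueError, match="labeled wells"):
            modeling.split_wells(layout, mode="well")


class TestOversampling:
    def test_balanced_input_unchanged(self):
        X = np.arange(8).reshape(4, 2).astype(float)
        y = np.array([0, 0, 1, 1])
        Xo, yo = modeling.oversample_minority(X, y)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)

    def test_two_point_minority_interpolates_on_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[5.0, 5.0]] * 5)
        y = np.array([1, 1, 0, 0, 0, 0, 0])
        Xo, yo, parents = modeling.oversample_minority(
            X, y, k_neighbors=1, seed=0, return_parents=True
        )
        assert (yo == 1).sum() == (yo == 0).sum() == 5
        synth = Xo[len(X):]
        # every synthetic point is t*(1,1) for t in [0,1]
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert ((synth >= 0.0) & (synth <= 1.0)).all()
        for (pi, qi, u), pt in zip(parents, synth):
            expect = X[y == 1][pi] + u * (X[y == 1][qi] - X[y == 1][pi])
            assert np.allclose(pt, expect)

    def test_imbalance_equalized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        y = np.array([1] * 10 + [0] * 90)
        Xo, yo = modeling.oversample_minority(X, y, seed=1)
        assert (yo == 1).sum() == (yo == 0).sum() == 90

    def test_convex_hull_property(self):
        """Each synthetic point lies on the segment between its parents."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        y = np.array([1] * 8 + [0] * 32)
        Xm = X[y == 1]
        Xo, yo, parents = modeling.oversample_minority(X, y, seed=2, return_parents=True)
        synth = Xo[len(X):]
        for (pi, qi, u), pt in zip(parents, synth):
            assert np.allclose(pt, Xm[pi] + u * (Xm[qi] - Xm[pi]), atol=1e-12)
            assert 0.0 <= u <= 1.0

    def test_singleton_minority_duplicated(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0], [0.1, 0.1], [0.2, 0.0]])
        y = np.array([1, 0, 0, 0])
        Xo, yo = modeling.oversample_minority(X, y)
        assert (yo == 1).sum() == 3
        assert np.allclose(Xo[len(X):], [1.0, 2.0])


class TestFeatureSelection:
    def _df(self, seed=0, n=200, p=10):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"F{i:02d}" for i in range(p)])

    def test_correlated_pair_pruned(self):
        df = self._df(seed=1)
        df["F09"] = df["F00"] * 1.0000001
        out = modeling.select_features(df, None, "correlation", max_correlation=0.95)
        assert ("F00" in out) != ("F09" in out)

    def test_anova_finds_informative_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = self._df(seed=seed)
            y = rng.integers(0, 2, len(df))
            df["F00"] = df["F00"] + 2.0 * y
            out = modeling.select_features(df, y, "anova_f", size=1)
            hits += out == ["F00"]
        assert hits >= 19

    def test_random_reproducible_and_sized(self):
        df = self._df()
        a = modeling.select_features(df, None, "random", seed=5, size=4)
        b = modeling.select_features(df, None, "random", seed=5, size=4)
        assert a == b and len(a) == 4

    def test_variance_drops_constant(self):
        df = self._df()
        df["F00"] = 1.0
        out = modeling.select_features(df, None, "variance")
        assert "F00" not in out

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            modeling.select_features(self._df(), None, "random", size=99)


class TestEvaluateModel:
    def test_perfect_separation(self):
        auc, mcc = modeling.evaluate_model(
            np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])
        )
        assert auc == 1.0 and mcc == 1.0

    def test_pairwise_concordance_example(self):
        # pos {0.8, 0.3}, neg {0.5, 0.1}: 3 of 4 pairs concordant
        auc, _ = modeling.evaluate_model(
            np.array([0.8, 0.3, 0.5, 0.1]), np.array([1, 1, 0, 0])
        )
        assert np.isclose(auc, 0.75)

    def test_mcc_balanced_confusion_is_zero(self):
        # TP=TN=FP=FN=1 -> MCC 0 by the defining formula
        scores = np.array([0.9, 0.1, 0.9, 0.1])
        labels = np.array([1, 1, 0, 0])
        _, mcc = modeling.evaluate_model(scores, labels)
        assert mcc == 0.0

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single-class"):
            modeling.evaluate_model(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_auc_equals_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n_pos = int(rng.integers(5, 100))
            n_neg = int(rng.integers(5, 100))
            scores, labels = two_class_scores(rng, n_pos, n_neg)
            if rng.random() < 0.5:  # inject ties
                scores = np.round(scores, 1)
            auc, _ = modeling.evaluate_model(scores, labels)
            assert abs(auc - pairwise_concordance_auc(scores, labels)) < 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_transform_leaves_auc_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = two_class_scores(rng, 20, 20)
        auc1, _ = modeling.evaluate_model(1 / (1 + np.exp(-scores)), labels)
        auc2, _ = modeling.evaluate_model(1 / (1 + np.exp(-(3 * scores + 2))), labels)
        assert abs(auc1 - auc2) < 1e-12


class TestMetaFeature:
    def _setup(self, scores_by_well):
        rows, score_rows = [], {}
        layout = pd.DataFrame(
            {
                "plate": ["P1"] * len(scores_by_well),
                "well": list(scores_by_well),
                "well_index": range(len(scores_by_well)),
                "role": "unlabeled_mix",
                "positive_fraction": [f for f, _ in scores_by_well.values()],
            }
        )
        i = 0
        for well, (_, scores) in scores_by_well.items():
            for s in scores:
                rows.append({"cell_id": f"c{i}", "plate": "P1", "well": well})
                score_rows[f"c{i}"] = s
                i += 1
        return pd.Series(score_rows), pd.DataFrame(rows), layout

    def test_balanced_extremes_zero_deviation(self):
        scores, cells, layout = self._setup({"W1": (0.5, [0.05] * 50 + [0.95] * 50)})
        dev, table = modeling.meta_feature_check(scores, cells, layout)
        assert dev == 0.0

    def test_all_high_on_90_10_wt_well(self):
        scores, cells, layout = self._setup({"W1": (0.1, [0.95] * 40)})
        dev, _ = modeling.meta_feature_check(scores, cells, layout)
        assert np.isclose(dev, 0.9)

    def test_all_excluded_worst_case(self):
        scores, cells, layout = self._setup({"W1": (0.5, [0.5] * 30)})
        dev, table = modeling.meta_feature_check(scores, cells, layout)
        assert dev == 1.0
        assert table["n_eligible"].iloc[0] == 0

    def test_no_unlabeled_wells_nan(self):
        scores, cells, layout = self._setup({"W1": (0.5, [0.9] * 5)})
        layout["role"] = "labeled_wt"
        dev, table = modeling.meta_feature_check(scores, cells, layout)
        assert np.isnan(dev) and table.empty


class TestSelection:
    def _result(self, auc_test, auc_train, meta=0.0, n_feat=4, tag="a"):
        spec = modeling.ModelSpec(
            algorithm="logistic",
            regularization=1.0,
            feature_subset=tuple(f"{tag}{i}" for i in range(n_feat)),
        )
        return modeling.ModelResult(
            spec=spec, auc_test=auc_test, auc_train=auc_train, meta_deviation=meta
        )

    def test_small_gap_wins_within_tolerance(self):
        a = self._result(0.90, 0.99, tag="a")  # gap 0.09
        b = self._result(0.89, 0.90, tag="b")  # gap 0.01
        assert modeling.select_pick_model([a, b]) is b

    def test_identical_metrics_hash_tiebreak_stable(self):
        a = self._result(0.9, 0.92, tag="a")
        b = self._result(0.9, 0.92, tag="b")
        first = modeling.select_pick_model([a, b])
        second = modeling.select_pick_model([b, a])
        assert first is second

    def test_single_model_chosen(self):
        a = self._result(0.7, 0.8)
        assert modeling.select_pick_model([a]) is a

    def test_all_failed_raises(self):
        a = self._result(0.7, 0.8)
        a.failed = True
        with pytest.raises(ValueError):
            modeling.select_pick_model([a])


class TestEnsemble:
    def test_mean_of_members(self):
        idx = ["c1", "c2"]
        r1 = modeling.ModelResult(
            spec=modeling.ModelSpec("logistic", 1.0, ("f",)),
            scores=pd.Series([0.2, 0.4], index=idx),
        )
        r2 = modeling.ModelResult(
            spec=modeling.ModelSpec("ridge", 1.0, ("f",)),
            scores=pd.Series([0.8, 0.4], index=idx),
        )
        ens = modeling.ensemble_predict([r1, r2])
        assert np.allclose(ens.to_numpy(), [0.5, 0.4])

    def test_identical_members_equal_member(self):
        r = modeling.ModelResult(
            spec=modeling.ModelSpec("logistic", 1.0, ("f",)),
            scores=pd.Series([0.3, 0.7], index=["c1", "c2"]),
        )
        ens = modeling.ensemble_predict([r, r])
        assert np.allclose(ens.to_numpy(), r.scores.to_numpy())

    def test_too_few_members(self):
        r = modeling.ModelResult(
            spec=modeling.ModelSpec("logistic", 1.0, ("f",)),
            scores=pd.Series([0.3], index=["c1"]),
        )
        with pytest.raises(ValueError):
            modeling.ensemble_predict([r])


class TestGridTraining:
    def test_separable_toy_reaches_auc_one(self):
        cells = pd.DataFrame(
            {
                "cell_id": ["a", "b", "c", "d"],
                "plate": "P1",
                "well": "W1",
                "F1": [0.0, 0.1, 1.0, 1.1],
                "F2": [0.0, 0.0, 1.0, 1.0],
            }
        )
        labels = pd.Series([0, 0, 1, 1], index=["a", "b", "c", "d"])
        spec = modeling.ModelSpec("logistic", 1.0, ("F1", "F2"))
        (res,) = modeling.train_model_grid(
            cells, labels, [spec],
            train_ids=np.array(["a", "b", "c", "d"]),
            test_ids=np.array(["a", "b", "c", "d"]),
            oversample=False,
        )
        assert res.auc_test == 1.0
        assert res.scores.between(0, 1).all()

    def test_label_shuffle_null_centered(self):
        """Mean test AUC over shuffled labels sits at 0.5 +- 0.05."""
        rng = np.random.default_rng(0)
        n = 160
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "plate": "P1",
                "well": "W1",
                "F1": rng.normal(size=n),
                "F2": rng.normal(size=n),
            }
        )
        ids = cells["cell_id"].to_numpy()
        train, test = ids[: n // 2], ids[n // 2 :]
        spec = modeling.ModelSpec("logistic", 1.0, ("F1", "F2"))
        aucs = []
        for s in range(50):
            labels = pd.Series(np.random.default_rng(s).integers(0, 2, n), index=ids)
            if labels.loc[train].nunique() < 2 or labels.loc[test].nunique() < 2:
                continue
            (res,) = modeling.train_model_grid(
                cells, labels, [spec], train, test, oversample=False
            )
            aucs.append(res.auc_test)
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_grid_count_contract(self, small_sim):
        cfg, cells, layout, truth = small_sim
        run = workflow.run_modeling(cfg)
        specs = {r.spec for r in run.model_results}
        assert len(run.model_results) == len(specs)
        assert len(run.model_results) >= 100  # a few-hundred-model grid
        ok = [r for r in run.model_results if not r.failed]
        assert len(ok) > 0.9 * len(run.model_results)

    def test_ensemble_at_least_min_member(self, small_sim):
        """Averaging decent models rarely falls below the worst member."""
        cfg, *_ = small_sim
        run = workflow.run_modeling(cfg)
        ok = sorted(
            (r for r in run.model_results if not r.failed),
            key=lambda r: -r.auc_test,
        )[:5]
        labels = run.labels
        test_ids = run.test_ids
        ens = modeling.ensemble_predict(ok)
        auc_ens, _ = modeling.evaluate_model(
            ens.loc[test_ids].to_numpy(), labels.loc[test_ids].to_numpy(int)
        )
        assert auc_ens >= min(r.auc_test for r in ok) - 0.01
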