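from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sppe.ensemble import (
    GroupLeakageError,
    SPPeModel,
    VoteWeights,
    build_dataset,
    evaluate_folds,
    grouped_kfold_evaluate,
    kennard_stone_split,
    load_model,
    loso_evaluate,
    make_classifier,
    predict_dataset,
    predict_sample,
    save_model,
    train,
    vote,
)
from sppe.features import FEATURE_NAMES
from sppe.metrics import report_from_predictions

from .conftest import synthetic_region_table
from .oracles import kennard_stone_loops


class TestVoteWeights:
    def test_defaults_balance_levels(self):
        w = VoteWeights()
        assert 4 * w.w1 == pytest.approx(16 * w.w2)
        assert w.total == pytest.approx(8 / 3)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            VoteWeights(w1=0.0)
        with pytest.raises(ValueError):
            VoteWeights(w2=-1.0)


class TestVoteArithmetic:
    LEVELS = [1] * 4 + [2] * 16

    def test_unanimous_score(self):
        label, scores = vote(["A"] * 20, self.LEVELS, VoteWeights(), ["A", "B"])
        assert label == "A"
        assert scores["A"] == pytest.approx(8 / 3)
        assert scores["B"] == 0.0

    def test_level_block_tie_uses_level0(self):
        preds = ["A"] * 4 + ["B"] * 16
        label, scores = vote(
            preds, self.LEVELS, VoteWeights(), ["A", "B"], level0_prediction="B"
        )
        assert scores["A"] == pytest.approx(scores["B"]) == pytest.approx(4 / 3)
        assert label == "B"

    def test_mixed_tie_and_weight_perturbation(self):
        preds = ["A"] * 3 + ["B"] + ["A"] * 4 + ["B"] * 12
        label, scores = vote(
            preds, self.LEVELS, VoteWeights(), ["A", "B"], level0_prediction="A"
        )
        assert scores["A"] == pytest.approx(4 / 3)
        assert scores["B"] == pytest.approx(4 / 3)
        assert label == "A"  # tie resolved by the level-0 prediction
        label2, scores2 = vote(
            preds, self.LEVELS, VoteWeights(w2=1 / 13), ["A", "B"]
        )
        assert scores2["A"] > scores2["B"]
        assert label2 == "A"

    def test_tie_falls_back_to_majority(self):
        preds = ["A"] * 4 + ["B"] * 16
        label, _ = vote(preds, self.LEVELS, VoteWeights(), ["A", "B"], fallback="A")
        assert label == "A"

    def test_score_mass_conserved(self, rng):
        w = VoteWeights(w1=0.21, w2=0.057)
        preds = [str(rng.choice(["A", "B", "C"])) for _ in range(20)]
        _, scores = vote(preds, self.LEVELS, w, ["A", "B", "C"])
        assert sum(scores.values()) == pytest.approx(4 * w.w1 + 16 * w.w2)

    def test_flipping_level1_votes_moves_four_thirds(self):
        preds_a = ["A"] * 4 + ["B"] * 16
        preds_b = ["B"] * 4 + ["B"] * 16
        _, sa = vote(preds_a, self.LEVELS, VoteWeights(), ["A", "B"], fallback="A")
        _, sb = vote(preds_b, self.LEVELS, VoteWeights(), ["A", "B"], fallback="A")
        assert sb["B"] - sa["B"] == pytest.approx(4 / 3)


class TestKennardStone:
    def test_line_extremes_chosen_first(self):
        x = np.array([[0.0], [1.0], [10.0]])
        train_idx, test_idx = kennard_stone_split(x, 2)
        assert list(train_idx) == [0, 2]
        assert list(test_idx) == [1]

    def test_proportions_90_of_110(self, rng):
        x = rng.normal(size=(110, 5))
        train_idx, test_idx = kennard_stone_split(x, 90)
        assert len(train_idx) == 90 and len(test_idx) == 20
        assert round(100 * len(train_idx) / 110, 1) == 81.8
        assert round(100 * len(test_idx) / 110, 1) == 18.2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rs = np.random.default_rng(seed)
        n = int(rs.integers(5, 13))
        x = rs.normal(size=(n, 3))
        n_train = int(rs.integers(2, n))
        train_idx, _ = kennard_stone_split(x, n_train)
        assert list(train_idx) == kennard_stone_loops(x, n_train)

    def test_deterministic(self, rng):
        x = rng.normal(size=(20, 4))
        a = kennard_stone_split(x, 12)
        b = kennard_stone_split(x, 12)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_bad_n_train(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            kennard_stone_split(x, 5)


class TestBuildDataset:
    def test_sppe_rows_per_sample(self, region_table):
        ds = build_dataset(region_table, mode="sppe")
        assert len(ds) == 6 * 20
        assert (ds.groupby("sample_id").size() == 20).all()
        assert (ds["level"] >= 1).all()

    def test_traditional_one_row_per_sample(self, region_table):
        ds = build_dataset(region_table, mode="traditional")
        assert len(ds) == 6
        assert (ds["level"] == 0).all()

    def test_spp_width_1155(self, region_table):
        ds = build_dataset(region_table, mode="spp")
        wide = [c for c in ds.columns if c not in ("sample_id", "label")]
        assert len(wide) == 1155
        assert len(ds) == 6

    def test_spp_concatenation_order(self, region_table):
        ds = build_dataset(region_table, mode="spp")
        row = ds.iloc[0]
        sid = row["sample_id"]
        src = region_table[
            (region_table.sample_id == sid)
            & (region_table.level == 2)
            & (region_table.tile_index == 15)
        ]
        assert row[f"{FEATURE_NAMES[0]}_L2T15"] == src[FEATURE_NAMES[0]].iloc[0]

    def test_missing_regions_named(self, region_table):
        broken = region_table.drop(region_table.index[0])
        with pytest.raises(ValueError, match="S00"):
            build_dataset(broken, mode="sppe")

    def test_bad_mode(self, region_table):
        with pytest.raises(ValueError):
            build_dataset(region_table, mode="pyramid")


class TestTrainPredict:
    def test_train_and_predict_sppe(self, region_table):
        model = SPPeModel(base=make_classifier("tree"))
        train(model, build_dataset(region_table, mode="sppe"))
        assert model.is_fitted
        preds = predict_dataset(model, region_table)
        assert len(preds) == 6
        assert set(preds["prediction"]) <= {"malting", "naked"}
        # perfect separation on clean synthetic features
        assert (preds["prediction"] == preds["truth"]).all()

    def test_score_columns_sum_to_total(self, region_table):
        model = SPPeModel(base=make_classifier("tree"))
        train(model, build_dataset(region_table, mode="sppe"))
        preds = predict_dataset(model, region_table)
        total = preds[["score_malting", "score_naked"]].sum(axis=1)
        assert np.allclose(total, 8 / 3)

    def test_single_class_raises(self, region_table):
        one = region_table[region_table.label == "malting"]
        model = SPPeModel(base=make_classifier("tree"))
        with pytest.raises(ValueError, match="single class"):
            train(model, build_dataset(one, mode="sppe"))

    def test_untrained_predict_raises(self, region_table):
        model = SPPeModel(base=make_classifier("tree"))
        with pytest.raises(ValueError, match="not trained"):
            predict_dataset(model, region_table)

    def test_predict_sample_requires_sppe_mode(self, region_table):
        model = SPPeModel(base=make_classifier("tree"), mode="traditional")
        train(model, build_dataset(region_table, mode="traditional"))
        with pytest.raises(ValueError, match="sppe"):
            predict_sample(model, object())

    def test_save_load_roundtrip(self, region_table, tmp_path):
        model = SPPeModel(base=make_classifier("tree"), weights=VoteWeights(0.5, 0.125))
        train(model, build_dataset(region_table, mode="sppe"))
        p = tmp_path / "model.sppe"
        save_model(model, p)
        loaded = load_model(p)
        assert loaded.weights == model.weights
        assert loaded.classes_ == model.classes_
        a = predict_dataset(model, region_table)
        b = predict_dataset(loaded, region_table)
        assert (a["prediction"] == b["prediction"]).all()


class SpyClassifier:
    """Records the rows it is fitted on and asked to predict."""

    def __init__(self, registry: list):
        self.registry = registry
        registry.append(self)
        self.fit_rows: set[bytes] = set()
        self.predict_rows: set[bytes] = set()

    def get_params(self, deep=False):
        return {"registry": self.registry}

    def fit(self, x, y):
        self.fit_rows = {np.asarray(r).tobytes() for r in x}
        self.classes_, counts = np.unique(y, return_counts=True)
        self.default_ = self.classes_[np.argmax(counts)]
        return self

    def predict(self, x):
        self.predict_rows |= {np.asarray(r).tobytes() for r in x}
        return np.full(len(x), self.default_)


class TestGroupedEvaluation:
    def test_loso_fold_counts(self):
        table = synthetic_region_table(n_samples=5)
        spies: list[SpyClassifier] = []
        loso_evaluate(table, mode="sppe", classifier=lambda: SpyClassifier(spies))
        assert len(spies) == 5
        for spy in spies:
            assert len(spy.fit_rows) == 4 * 20  # 4 training samples x 20 rows

    def test_no_leakage_loso(self):
        table = synthetic_region_table(n_samples=6, seed=3)
        spies: list[SpyClassifier] = []
        loso_evaluate(table, mode="sppe", classifier=lambda: SpyClassifier(spies))
        for spy in spies:
            assert not (spy.fit_rows & spy.predict_rows)

    def test_no_leakage_grouped_kfold(self):
        table = synthetic_region_table(n_samples=8, seed=4)
        spies: list[SpyClassifier] = []
        grouped_kfold_evaluate(
            table, n_splits=4, mode="sppe", classifier=lambda: SpyClassifier(spies)
        )
        assert len(spies) == 4
        for spy in spies:
            assert not (spy.fit_rows & spy.predict_rows)

    def test_kfold_partitions_samples(self):
        table = synthetic_region_table(n_samples=9, seed=5)
        preds = grouped_kfold_evaluate(table, n_splits=3, mode="sppe")
        assert sorted(preds["sample_id"]) == sorted(table["sample_id"].unique())

    def test_explicit_overlap_raises(self, region_table):
        ids = set(region_table["sample_id"].unique())
        folds = [(ids, {"S00"})]  # S00 in both sides
        with pytest.raises(GroupLeakageError):
            evaluate_folds(region_table, folds, mode="sppe")

    def test_separable_data_loso_perfect(self):
        table = synthetic_region_table(n_samples=8, sep=10.0, noise=0.5, seed=1)
        preds = loso_evaluate(table, mode="sppe", classifier="tree", seed=0)
        rep = report_from_predictions(preds)
        assert rep["accuracy"] == 1.0

    def test_loso_needs_three_samples(self):
        table = synthetic_region_table(n_samples=2)
        with pytest.raises(ValueError):
            loso_evaluate(table, mode="sppe")

    @pytest.mark.parametrize("mode", ["traditional", "spp"])
    def test_baseline_modes_run(self, mode):
        table = synthetic_region_table(n_samples=6, seed=2)
        preds = loso_evaluate(table, mode=mode, classifier="tree")
        assert len(preds) == 6
        rep = report_from_predictions(preds)
        assert rep["accuracy"] == 1.0  # separable either way


class TestClassifierRegistry:
    @pytest.mark.parametrize("name", ["knn", "tree", "rf", "svm"])
    def test_constructible_and_fittable(self, name, rng):
        clf = make_classifier(name, seed=0)
        x = rng.normal(size=(40, 55))
        y = np.array(["a", "b"] * 20)
        clf.fit(x, y)
        assert set(clf.predict(x)) <= {"a", "b"}

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            make_classifier("perceptron")
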