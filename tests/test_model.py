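"""Splits, subset enumeration, grid search, selection, importance and
persistence of the efficacy model."""

import math

import numpy as np
import pandas as pd
import pytest

from exonskip.features import CONCENTRATION_FEATURE
from exonskip.model import (
    DEFAULT_GRID,
    SMALL_GRID,
    HyperGrid,
    ModelPersistenceError,
    SearchConfig,
    TrainingData,
    enumerate_feature_subsets,
    grid_search_fit,
    load_model,
    permutation_importance,
    r_squared,
    save_model,
    select_model,
    split_train_test,
    validation_splits,
)


def _toy_data(n_groups=20, per_group=2, seed=0, n_features=3):
    rng = np.random.default_rng(seed)
    rows, ys, groups = [], [], []
    for g in range(n_groups):
        seq = "".join(rng.choice(list("ACGU"), size=15))
        for _ in range(per_group):
            x = rng.normal(size=n_features)
            rows.append({CONCENTRATION_FEATURE: abs(x[0]) + 0.1,
                         **{f"f{i}": x[i] for i in range(1, n_features)}})
            ys.append(50 + 20 * x[0] + rng.normal() * 2 + g)
            groups.append(seq)
    return TrainingData(pd.DataFrame(rows), np.array(ys), np.array(groups, dtype=object))


class TestRSquared:
    def test_perfect_linear_relation(self):
        y = np.arange(10.0)
        assert r_squared(y, 2 * y + 3) == pytest.approx(1.0)

    def test_constant_prediction_undefined(self):
        assert math.isnan(r_squared(np.arange(5.0), np.ones(5)))


class TestSplits:
    def test_train_test_group_counts_and_disjointness(self):
        data = _toy_data(n_groups=20)
        train, test = split_train_test(data, test_frac=0.10, seed=0)
        assert len(set(test.groups)) == 2
        assert set(train.groups).isdisjoint(set(test.groups))
        assert len(train) + len(test) == len(data)

    def test_same_seed_reproduces_split(self):
        data = _toy_data()
        a = split_train_test(data, seed=11)
        b = split_train_test(data, seed=11)
        assert list(a[1].groups) == list(b[1].groups)

    def test_stratification_spreads_test_groups_across_bins(self):
        data = _toy_data(n_groups=100, per_group=1, seed=2)
        train, test = split_train_test(data, test_frac=0.10, seed=3, n_bins=5)
        # per-quintile test fraction within one group of 10%
        means = pd.DataFrame({"g": data.groups, "y": data.y}).groupby("g")["y"].mean()
        bins = pd.qcut(means.rank(method="first"), 5, labels=False)
        test_groups = set(test.groups)
        for b in range(5):
            members = set(means.index[bins == b])
            assert abs(len(members & test_groups) - 2) <= 1

    def test_too_few_groups_rejected(self):
        data = _toy_data(n_groups=5)
        with pytest.raises(ValueError, match="at least 10"):
            split_train_test(data)

    def test_validation_splits_partition_and_disjoint(self):
        data = _toy_data(n_groups=15)
        splits = validation_splits(data, n_repeats=10, seed=4)
        assert len(splits) == 10
        for bidx, vidx in splits:
            assert set(data.groups[bidx]).isdisjoint(set(data.groups[vidx]))
            assert sorted(np.concatenate([bidx, vidx])) == list(range(len(data)))

    def test_single_repeat(self):
        data = _toy_data(n_groups=15)
        assert len(validation_splits(data, n_repeats=1, seed=0)) == 1


class TestGridSearch:
    def test_single_point_grid_returns_it(self):
        data = _toy_data()
        grid = HyperGrid(C=(10.0,), gamma=(0.1,), epsilon=(0.1,))
        point, r2 = grid_search_fit(data.X[:30], data.y[:30], data.X[30:], data.y[30:], grid)
        assert point == (10.0, 0.1, 0.1)
        assert np.isfinite(r2)

    def test_planted_linear_target_reaches_high_r2(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({CONCENTRATION_FEATURE: rng.uniform(0.1, 10, 200),
                          "f1": rng.normal(size=200)})
        y = 40 + 4 * X[CONCENTRATION_FEATURE] + 10 * X["f1"] + rng.normal(size=200)
        point, r2 = grid_search_fit(X[:160], y[:160], X[160:], y[160:], DEFAULT_GRID)
        assert r2 >= 0.9

    def test_superset_grid_never_decreases_best_score(self):
        data = _toy_data(seed=5)
        small = HyperGrid(C=(1.0, 10.0), gamma=(0.1,), epsilon=(0.1,))
        big = HyperGrid(C=(0.1, 1.0, 10.0, 100.0), gamma=(0.01, 0.1), epsilon=(0.1, 1.0))
        _, r2_small = grid_search_fit(data.X[:30], data.y[:30], data.X[30:], data.y[30:], small)
        _, r2_big = grid_search_fit(data.X[:30], data.y[:30], data.X[30:], data.y[30:], big)
        assert r2_big >= r2_small - 1e-12

    def test_degenerate_validation_target_skipped(self):
        data = _toy_data()
        point, r2 = grid_search_fit(data.X[:30], data.y[:30], data.X[30:35],
                                    np.full(5, 42.0), SMALL_GRID)
        assert point is None and math.isnan(r2)


class TestSubsetEnumeration:
    def test_small_pool_count(self):
        subsets = enumerate_feature_subsets(
            [CONCENTRATION_FEATURE, "a", "b", "c", "d"], max_features=3)
        assert len(subsets) == 11  # 1 + C(4,1) + C(4,2)

    def test_forced_only(self):
        subsets = enumerate_feature_subsets([CONCENTRATION_FEATURE], max_features=6)
        assert subsets == [(CONCENTRATION_FEATURE,)]

    def test_every_subset_contains_forced_and_respects_bound(self):
        names = [CONCENTRATION_FEATURE] + [f"f{i}" for i in range(6)]
        subsets = enumerate_feature_subsets(names, max_features=4)
        assert all(CONCENTRATION_FEATURE in s for s in subsets)
        assert all(len(s) <= 4 for s in subsets)
        assert len(set(subsets)) == len(subsets)
        assert len(subsets) == sum(math.comb(6, k) for k in range(0, 4))

    def test_missing_forced_feature_rejected(self):
        with pytest.raises(ValueError, match="forced"):
            enumerate_feature_subsets(["a", "b"], forced=(CONCENTRATION_FEATURE,))


class TestSelection:
    def test_single_subset_registry_wins(self):
        data = _toy_data(n_groups=20, per_group=3, seed=1)
        config = SearchConfig(max_features=1, n_repeats=4,
                              grid=HyperGrid((1.0,), (0.1,), (0.1,)), seed=0)
        search, model = select_model(data, config)
        assert model.spec.feature_names == (CONCENTRATION_FEATURE,)
        assert len(search.table) == 1

    def test_winner_has_maximal_mean_r2(self):
        data = _toy_data(n_groups=20, per_group=3, seed=1)
        config = SearchConfig(max_features=2, n_repeats=6, grid=SMALL_GRID, seed=0)
        search, model = select_model(data, config)
        best = search.table.loc[search.table["subset"] == model.spec.feature_names,
                                "mean_r2"].iloc[0]
        assert best >= search.table["mean_r2"].max() - 1e-12

    def test_selection_invariant_to_feature_column_order(self):
        data = _toy_data(n_groups=20, per_group=3, seed=1)
        config = SearchConfig(max_features=2, n_repeats=6, grid=SMALL_GRID, seed=0)
        _, model_a = select_model(data, config)
        reordered = TrainingData(data.X[list(data.X.columns)[::-1]], data.y, data.groups)
        _, model_b = select_model(reordered, config)
        assert model_a.spec.feature_names == model_b.spec.feature_names


class TestPredict:
    def test_row_permutation_permutes_predictions(self, toy_model, small_training_data):
        X = small_training_data.X
        perm = np.random.default_rng(0).permutation(len(X))
        direct = toy_model.predict(X)[perm]
        shuffled = toy_model.predict(X.iloc[perm])
        assert np.allclose(direct, shuffled, atol=1e-12)

    def test_missing_feature_named_in_error(self, toy_model):
        with pytest.raises(KeyError, match="ACP"):
            toy_model.predict(pd.DataFrame({CONCENTRATION_FEATURE: [3.0],
                                            "GCs (number of)": [5.0]}))


class TestImportance:
    def test_unused_feature_has_exactly_zero_importance(self, toy_model,
                                                        small_training_data):
        report = permutation_importance(toy_model, small_training_data.X,
                                        small_training_data.y, n_repeats=5, seed=0)
        table = report.table.set_index("feature")
        assert table.at["decoy_noise", "mean_importance"] == 0.0
        assert table.at["decoy_noise", "sd_importance"] == 0.0

    def test_model_features_have_rows(self, toy_model, small_training_data):
        report = permutation_importance(toy_model, small_training_data.X,
                                        small_training_data.y, n_repeats=5, seed=0)
        assert set(report.table["feature"]) == set(small_training_data.X.columns)


class TestPersistence:
    def test_round_trip_predictions_identical(self, toy_model, small_training_data,
                                              tmp_path):
        path = tmp_path / "model.joblib"
        save_model(toy_model, path)
        loaded = load_model(path)
        X = small_training_data.X
        assert np.allclose(toy_model.predict(X), loaded.predict(X), atol=1e-12)
        assert loaded.metadata == toy_model.metadata
        assert loaded.spec == toy_model.spec

    def test_corrupted_archive_raises_cleanly(self, tmp_path):
        path = tmp_path / "model.joblib"
        path.write_bytes(b"not a model")
        with pytest.raises(ModelPersistenceError):
            load_model(path)

    def test_hash_mismatch_warns(self, toy_model, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(toy_model, path)
        with pytest.warns(UserWarning, match="hash"):
            load_model(path, expected_data_hash="deadbeef")
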