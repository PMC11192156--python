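import numpy as np
import pandas as pd
import pytest

from seedscan.classifier import (
    ForestConfig,
    importance_filter_refit,
    load_model,
    predict_species,
    save_model,
    train_forest,
    tune_forest,
)
from seedscan.features import RESPONSE_COLUMN, default_predictors, split_train_test


def separable_frame(n_each=40, seed=0, noise_col=False):
    """Two species with disjoint Area ranges; everything else is noise."""
    rng = np.random.default_rng(seed)
    size_family = ("Area", "Perim", "Major", "Minor", "Feret", "IntDen")
    rows = []
    for sp, lo, hi in (("AAA", 0.1, 0.4), ("BBB", 0.8, 1.2)):
        for _ in range(n_each):
            row = {c: rng.normal() for c in default_predictors() if c != "Site"}
            size = rng.uniform(lo, hi)
            for c in size_family:
                row[c] = size * rng.uniform(0.9, 1.1)
            row["Site"] = rng.choice(["S01", "S02"])
            row[RESPONSE_COLUMN] = sp
            if noise_col:
                row["Noise"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestTrainForest:
    def test_separable_oob_zero(self):
        model = train_forest(separable_frame(), ForestConfig(ntree=50, rng_seed=1))
        assert model.oob_error == 0.0

    def test_determinism(self):
        df = separable_frame(seed=3)
        m1 = train_forest(df, ForestConfig(ntree=40, rng_seed=7))
        m2 = train_forest(df, ForestConfig(ntree=40, rng_seed=7))
        assert m1.importance.equals(m2.importance)
        assert m1.oob_error == m2.oob_error
        pd.testing.assert_frame_equal(predict_species(m1, df), predict_species(m2, df))

    def test_row_permutation_invariance(self):
        df = separable_frame(seed=4)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        m1 = train_forest(df, ForestConfig(ntree=30, rng_seed=5))
        m2 = train_forest(shuffled, ForestConfig(ntree=30, rng_seed=5))
        assert m1.oob_error == m2.oob_error
        pd.testing.assert_frame_equal(predict_species(m1, df), predict_species(m2, df))

    def test_single_class_rejected(self):
        df = separable_frame()
        df[RESPONSE_COLUMN] = "AAA"
        with pytest.raises(ValueError, match="2 classes"):
            train_forest(df, ForestConfig(ntree=5))

    def test_synthetic_dataset_oob(self, small_table):
        model = train_forest(small_table, ForestConfig(ntree=200, rng_seed=1))
        assert model.oob_error < 0.15

    def test_importance_of_constant_predictor_is_zero(self):
        df = separable_frame(seed=6)
        df["Median"] = 0.0  # constant: never selected by any split
        model = train_forest(df, ForestConfig(ntree=30, rng_seed=2))
        assert model.importance["Median"] == 0.0

    def test_size_family_importance_on_synth_data(self, small_table):
        model = train_forest(small_table, ForestConfig(ntree=200, rng_seed=1))
        ranked = model.importance.sort_values(ascending=False).index.tolist()
        size_family = {"Area", "Perim", "Major", "Minor", "Feret", "IntDen"}
        top_half = set(ranked[: len(ranked) // 2])
        assert len(size_family & top_half) >= 4


class TestConfig:
    def test_default_mtry_floor_sqrt_26(self):
        assert ForestConfig().resolved_mtry(26) == 5

    @pytest.mark.parametrize("p,expected", [(4, 2), (9, 3), (25, 5), (26, 5), (35, 5), (36, 6)])
    def test_mtry_rule(self, p, expected):
        assert ForestConfig().resolved_mtry(p) == expected

    def test_explicit_mtry_bounds(self):
        with pytest.raises(ValueError):
            ForestConfig(mtry=30).resolved_mtry(26)
        with pytest.raises(ValueError):
            ForestConfig(ntree=0)


class TestPredict:
    def test_self_accuracy_near_perfect(self, small_table):
        train, _ = split_train_test(small_table, 0.8, rng_seed=0)
        model = train_forest(train, ForestConfig(ntree=100, rng_seed=0))
        calls = predict_species(model, train)
        acc = (calls["predicted"].to_numpy() == train[RESPONSE_COLUMN].to_numpy()).mean()
        assert acc > 0.99

    def test_single_tree_votes_binary(self):
        df = separable_frame()
        model = train_forest(df, ForestConfig(ntree=1, rng_seed=0))
        calls = predict_species(model, df)
        votes = calls[[c for c in calls if c.startswith("vote_")]].to_numpy()
        assert set(np.unique(votes)) <= {0.0, 1.0}

    def test_vote_fractions_sum_to_one_and_argmax(self):
        df = separable_frame(seed=8)
        model = train_forest(df, ForestConfig(ntree=25, rng_seed=3))
        calls = predict_species(model, df)
        vote_cols = [c for c in calls if c.startswith("vote_")]
        sums = calls[vote_cols].sum(axis=1)
        assert np.allclose(sums, 1.0)
        for _, row in calls.iterrows():
            winner = f"vote_{row['predicted']}"
            assert row[winner] == row[vote_cols].max()

    def test_empty_table(self):
        df = separable_frame()
        model = train_forest(df, ForestConfig(ntree=5, rng_seed=0))
        out = predict_species(model, df.iloc[0:0])
        assert out.empty and "predicted" in out.columns

    def test_unseen_site_fails_loudly(self):
        df = separable_frame()
        model = train_forest(df, ForestConfig(ntree=5, rng_seed=0))
        bad = df.head(3).copy()
        bad["Site"] = "S99"
        with pytest.raises(ValueError, match="S99"):
            predict_species(model, bad)

    def test_schema_mismatch_lists_missing(self):
        df = separable_frame()
        model = train_forest(df, ForestConfig(ntree=5, rng_seed=0))
        with pytest.raises(ValueError, match="Area"):
            predict_species(model, df.drop(columns=["Area"]))

    def test_save_load_roundtrip(self, tmp_path):
        df = separable_frame(seed=10)
        model = train_forest(df, ForestConfig(ntree=20, rng_seed=4))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        pd.testing.assert_frame_equal(predict_species(model, df), predict_species(back, df))
        assert back.class_labels == model.class_labels


class TestTune:
    def test_tiebreak_prefers_smaller_config(self):
        df = separable_frame(seed=2)
        grid, best = tune_forest(df, [100, 500], [5], rng_seed=0)
        assert (grid["oob_error"] == 0).all()
        assert (best.ntree, best.mtry) == (100, 5)

    def test_grid_shape(self, small_table):
        grid, best = tune_forest(
            small_table.sample(200, random_state=0),
            [25, 50, 100],
            [3, 5, 8],
            rng_seed=1,
        )
        assert len(grid) == 9
        assert best.ntree in (25, 50, 100) and best.mtry in (3, 5, 8)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_forest(separable_frame(), [], [5], 0)


class TestImportanceFilter:
    def test_threshold_zero_keeps_all_and_matches(self, small_table):
        train, test = split_train_test(small_table, 0.8, rng_seed=0)
        model = train_forest(train, ForestConfig(ntree=100, rng_seed=0))
        retained, acc, refit = importance_filter_refit(train, test, model, 0.0)
        assert retained == model.predictors
        base_calls = predict_species(model, test)
        base_acc = (
            base_calls["predicted"].to_numpy() == test[RESPONSE_COLUMN].to_numpy()
        ).mean()
        assert acc == pytest.approx(base_acc)

    def test_threshold_above_max_is_error(self):
        df = separable_frame(seed=5)
        model = train_forest(df, ForestConfig(ntree=20, rng_seed=0))
        with pytest.raises(ValueError, match="lower the threshold"):
            importance_filter_refit(df, df, model, model.importance.max() + 1)

    def test_noise_predictor_ranks_last_and_removal_is_benign(self):
        df = separable_frame(n_each=60, seed=12, noise_col=True)
        # every predictor here carries class signal except Noise
        preds = ["Area", "Perim", "Major", "Minor", "Feret", "IntDen", "Noise"]
        train = df.iloc[::2].reset_index(drop=True)
        test = df.iloc[1::2].reset_index(drop=True)
        model = train_forest(train, ForestConfig(ntree=100, rng_seed=0), predictors=preds)
        ranked = model.importance.sort_values().index.tolist()
        assert ranked[0] == "Noise"  # ranks last in importance
        thresh = max(float(model.importance["Noise"]), 1e-9)
        retained, acc, _ = importance_filter_refit(train, test, model, thresh)
        assert "Noise" not in retained
        base = predict_species(model, test)
        base_acc = (base["predicted"].to_numpy() == test[RESPONSE_COLUMN].to_numpy()).mean()
        assert abs(acc - base_acc) < 0.02
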