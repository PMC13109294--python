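import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from omicboost import (BoostConfig, OutcomeVector, ShapResult, SplitSpec,
                       ValidationError, boruta_shap, concat_blocks, fit,
                       make_splits, rank_features, shap_values, tune)

from conftest import make_block, make_metadata, make_outcome


def replicate_meta(n, n_groups):
    ids = [f"S{i:03d}" for i in range(n)]
    return ids, make_metadata(ids, replicate=[f"R{i % n_groups}"
                                              for i in range(n)])


class TestConcatBlocks:
    def test_prefixed_feature_union(self, rng):
        a = make_block(rng.standard_normal((5, 4)), name="tx")
        b = make_block(rng.standard_normal((3, 4)), name="ftir")
        out = concat_blocks([a, b])
        assert out.n_features == 8
        assert out.feature_ids[0] == "tx:f0"
        assert out.feature_ids[-1] == "ftir:f2"

    def test_single_block_identity_up_to_prefix(self, rng):
        a = make_block(rng.standard_normal((2, 3)), name="tx")
        out = concat_blocks([a])
        assert np.array_equal(out.values, a.values)
        assert out.feature_ids == ["tx:f0", "tx:f1"]

    def test_misaligned_samples_rejected(self, rng):
        a = make_block(np.ones((2, 2)), name="a", sample_ids=["x", "y"])
        b = make_block(np.ones((2, 2)), name="b", sample_ids=["y", "x"])
        with pytest.raises(ValidationError, match="align"):
            concat_blocks([a, b])

    def test_missingness_preserved(self, rng):
        x = rng.standard_normal((2, 3))
        x[1, 2] = np.nan
        out = concat_blocks([make_block(x, name="a")])
        assert np.isnan(out.values[1, 2])


class TestMakeSplits:
    def test_replicate_groups_never_straddle(self):
        ids, meta = replicate_meta(6, 3)
        spec = SplitSpec(mode="by_replicate", seed=1, n_repeats=5,
                         train_fraction=0.67)
        for train, test in make_splits(meta, spec):
            reps_train = {meta.factor("replicate")[s] for s in train}
            reps_test = {meta.factor("replicate")[s] for s in test}
            assert reps_train.isdisjoint(reps_test)
            assert sorted(train + test) == sorted(ids)

    def test_random_split_arithmetic(self):
        ids, meta = replicate_meta(20, 4)
        spec = SplitSpec(mode="random", train_fraction=0.75, seed=0)
        train, test = make_splits(meta, spec)[0]
        assert (len(train), len(test)) == (15, 5)

    def test_same_seed_reproduces_splits(self):
        _, meta = replicate_meta(12, 4)
        spec = SplitSpec(mode="by_replicate", seed=9)
        assert make_splits(meta, spec) == make_splits(meta, spec)

    def test_leave_group_out_one_split_per_level(self):
        _, meta = replicate_meta(12, 4)
        splits = make_splits(meta, SplitSpec(mode="leave_group_out"))
        assert len(splits) == 4
        held = [frozenset(meta.factor("replicate")[s] for s in test)
                for _, test in splits]
        assert len(set(held)) == 4

    def test_single_group_rejected(self):
        _, meta = replicate_meta(4, 1)
        with pytest.raises(ValidationError, match="levels"):
            make_splits(meta, SplitSpec(mode="by_replicate"))


class TestTune:
    def test_single_point_grid_returned_with_metrics(self, rng):
        block = make_block(rng.standard_normal((4, 24)))
        y = make_outcome(block.sample_ids, rng.standard_normal(24))
        res = tune(block, y, grid=[(30, 2)], cv_folds=4)
        assert (res.config.n_rounds, res.config.max_depth) == (30, 2)
        assert len(res.cv_results) == 1
        assert np.isfinite(res.cv_results["cv_rmse"].iloc[0])

    def test_depth_one_signal_selects_depth_one(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = rng.standard_normal((5, 60))
            y = np.where(x[0] > 0, 2.0, -1.0) + 0.1 * rng.standard_normal(60)
            block = make_block(x)
            res = tune(block, make_outcome(block.sample_ids, y),
                       grid=[(100, 1), (100, 6)], cv_folds=5,
                       base_config=BoostConfig(seed=seed))
            wins += res.config.max_depth == 1
        assert wins >= 8

    def test_loocv_evaluates_n_folds(self, rng):
        block = make_block(rng.standard_normal((3, 12)))
        y = make_outcome(block.sample_ids, rng.standard_normal(12))
        res = tune(block, y, grid=[(20, 2)], cv_folds="loo")
        assert np.isfinite(res.cv_results["cv_rmse"].iloc[0])

    def test_empty_grid_rejected(self, rng):
        block = make_block(rng.standard_normal((3, 10)))
        y = make_outcome(block.sample_ids, rng.standard_normal(10))
        with pytest.raises(ValidationError, match="grid"):
            tune(block, y, grid=[])

    def test_more_folds_than_samples_rejected(self, rng):
        block = make_block(rng.standard_normal((3, 4)))
        y = make_outcome(block.sample_ids, rng.standard_normal(4))
        with pytest.raises(ValidationError, match="folds"):
            tune(block, y, grid=[(20, 2)], cv_folds=10)


class TestFit:
    def test_mean_predictor_has_nonpositive_r2(self, rng):
        """A constant model can never beat the test-set mean."""
        x = rng.standard_normal((2, 40))
        y = rng.standard_normal(40)  # no learnable signal
        block = make_block(x)
        model = fit(block, make_outcome(block.sample_ids, y),
                    BoostConfig(seed=0, n_rounds=5, learning_rate=0.0),
                    SplitSpec(mode="random", seed=0))
        assert model.mean_metrics["r2"] <= 0.0

    def test_strong_signal_recovered_across_replicate_splits(self):
        rng = np.random.default_rng(7)
        n, p = 80, 501
        x = rng.standard_normal((p, n))
        signal = 3.0 * x[0]
        y = signal + 0.1 * signal.std() * rng.standard_normal(n)
        ids, meta = replicate_meta(n, 8)
        block = make_block(x, sample_ids=ids)
        model = fit(block, make_outcome(ids, y), BoostConfig(seed=1),
                    SplitSpec(mode="by_replicate", seed=1), meta)
        assert model.mean_metrics["r2"] >= 0.5
        assert len(model.metrics) == 3

    def test_zero_variance_training_outcome_rejected(self):
        ids, meta = replicate_meta(8, 4)
        block = make_block(np.random.default_rng(0).standard_normal((3, 8)),
                           sample_ids=ids)
        with pytest.raises(ValidationError, match="zero variance"):
            fit(block, make_outcome(ids, np.ones(8)), BoostConfig(),
                SplitSpec(mode="by_replicate", seed=0), meta)

    def test_missing_predictors_allowed(self, rng):
        x = rng.standard_normal((5, 30))
        x[rng.random((5, 30)) < 0.2] = np.nan
        block = make_block(x)
        y = make_outcome(block.sample_ids, rng.standard_normal(30))
        model = fit(block, y, BoostConfig(seed=0, n_rounds=10),
                    SplitSpec(mode="random", seed=0))
        assert np.isfinite(model.mean_metrics["rmse"])

    def test_same_seed_bitwise_reproducible(self, rng):
        x = rng.standard_normal((10, 30))
        y = rng.standard_normal(30)
        block = make_block(x)
        kw = dict(config=BoostConfig(seed=5, n_rounds=20),
                  split=SplitSpec(mode="random", seed=5))
        m1 = fit(block, make_outcome(block.sample_ids, y), **kw)
        m2 = fit(block, make_outcome(block.sample_ids, y), **kw)
        assert m1.metrics.equals(m2.metrics)

    def test_separable_classes_classified_perfectly(self):
        """Two classes split by a wide margin on one feature."""
        rng = np.random.default_rng(3)
        n = 60
        labels = (np.arange(n) % 2).astype(float)
        x = rng.standard_normal((5, n))
        x[0] = np.where(labels == 1, rng.uniform(1.0, 2.0, n),
                        rng.uniform(-2.0, -1.0, n))
        block = make_block(x)
        model = fit(block, make_outcome(block.sample_ids, labels,
                                        task="classification"),
                    BoostConfig(seed=3, objective="logistic", n_rounds=50),
                    SplitSpec(mode="random", seed=3))
        assert model.mean_metrics["accuracy"] == 1.0

    def test_objective_task_mismatch_rejected(self, rng):
        block = make_block(rng.standard_normal((3, 10)))
        y = make_outcome(block.sample_ids, rng.standard_normal(10))
        with pytest.raises(ValidationError, match="logistic"):
            fit(block, y, BoostConfig(objective="logistic"),
                SplitSpec(mode="random"))


class TestShapValues:
    def fitted(self, rng, monotone_y=False):
        n, p = 60, 6
        x = rng.standard_normal((p, n))
        if monotone_y:
            y = 2.0 * x[0] + np.abs(x[0]) * x[0] \
                + 0.1 * rng.standard_normal(n)
        else:
            y = 2.0 * x[0] - 1.5 * x[1] + 0.1 * rng.standard_normal(n)
        block = make_block(x)
        model = fit(block, make_outcome(block.sample_ids, y),
                    BoostConfig(seed=0, n_rounds=60),
                    SplitSpec(mode="random", seed=0))
        return block, model

    def test_local_accuracy(self, rng):
        block, model = self.fitted(rng)
        shap = shap_values(model, block)
        dmat = xgb.DMatrix(block.values.T, missing=np.nan,
                           feature_names=block.feature_ids)
        pred = model.booster.predict(dmat, output_margin=True)
        recon = shap.base_value + shap.attributions.sum(axis=1).to_numpy()
        assert np.max(np.abs(recon - pred)) < 1e-4

    def test_unused_feature_has_zero_attribution(self, rng):
        n = 50
        x = np.vstack([np.linspace(-1, 1, n), np.zeros(n)])
        y = 3.0 * x[0]
        block = make_block(x)
        model = fit(block, make_outcome(block.sample_ids, y),
                    BoostConfig(seed=0, n_rounds=30),
                    SplitSpec(mode="random", seed=0))
        shap = shap_values(model, block)
        assert np.allclose(shap.attributions["f1"], 0.0)

    def test_monotone_increasing_feature_gets_positive_direction(self, rng):
        block, model = self.fitted(rng, monotone_y=True)
        shap = shap_values(model, block)
        assert shap.direction["f0"] == 1

    def test_feature_mismatch_rejected(self, rng):
        block, model = self.fitted(rng)
        other = make_block(rng.standard_normal((3, 10)))
        with pytest.raises(ValidationError, match="features"):
            shap_values(model, other)


class TestRankFeatures:
    def fake_shap(self, importances, directions=None):
        feats = pd.Index(list(importances), name="feature")
        return ShapResult(
            pd.DataFrame(np.zeros((2, len(feats))), columns=feats),
            0.0,
            pd.Series(list(importances.values()), index=feats),
            pd.Series(directions or [0] * len(feats), index=feats))

    def test_sorted_descending_with_direction_column(self):
        table = rank_features(self.fake_shap(
            {"a": 0.1, "b": 0.9, "c": 0.5}, [1, -1, 0]))
        assert list(table["feature"]) == ["b", "c", "a"]
        assert "direction" in table.columns

    def test_ties_break_lexicographically(self):
        table = rank_features(self.fake_shap({"zz": 0.5, "aa": 0.5}))
        assert list(table["feature"]) == ["aa", "zz"]

    def test_top_n_larger_than_feature_count_returns_all(self):
        table = rank_features(self.fake_shap({"a": 1.0}), top_n=10)
        assert len(table) == 1


class TestBorutaShap:
    def test_strong_predictor_confirmed(self):
        rng = np.random.default_rng(0)
        n, p = 60, 8
        x = rng.standard_normal((p, n))
        y = 3.0 * x[0] + 0.3 * rng.standard_normal(n)
        block = make_block(x)
        dec = boruta_shap(block, make_outcome(block.sample_ids, y),
                          BoostConfig(seed=0, n_rounds=50), n_iter=20)
        assert dec.set_index("feature").loc["f0", "decision"] == "confirmed"

    def test_pure_noise_mostly_rejected(self):
        rng = np.random.default_rng(1)
        n, p = 60, 8
        block = make_block(rng.standard_normal((p, n)))
        y = make_outcome(block.sample_ids, rng.standard_normal(n))
        dec = boruta_shap(block, y, BoostConfig(seed=1, n_rounds=50),
                          n_iter=20)
        assert (dec["decision"] == "confirmed").sum() == 0

    def test_too_few_iterations_rejected(self, rng):
        block = make_block(rng.standard_normal((3, 20)))
        y = make_outcome(block.sample_ids, rng.standard_normal(20))
        with pytest.raises(ValidationError, match="n_iter"):
            boruta_shap(block, y, n_iter=0)
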