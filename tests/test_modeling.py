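"""Nested CV machinery: folds, one-SE tuning, stacking, metrics, BrainAGE."""

import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from eegage.modeling import (NCVConfig, brainage, compute_metrics, fit_stack,
                             learning_curve, make_folds, metrics_by_group,
                             run_ncv, tune_inner)

warnings.filterwarnings("ignore", category=UserWarning)
logging.getLogger("eegage").setLevel(logging.ERROR)


def linear_table(rng, n=60, p=8, noise=0.0):
    X = rng.normal(0, 1, (n, p))
    age = 38 + 5 * X[:, 0] - 3 * X[:, 1] + 2 * X[:, 2] \
        + noise * rng.normal(0, 1, n)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    df.insert(0, "age", age)
    return df


SMALL_METHODS = ["enet", "rf"]


class TestMakeFolds:
    def test_balanced_partition(self):
        labels = make_folds(100, 10, 0)
        _, counts = np.unique(labels, return_counts=True)
        assert counts.tolist() == [10] * 10

    def test_reproducible(self):
        assert np.array_equal(make_folds(57, 7, 42), make_folds(57, 7, 42))

    def test_uneven_sizes_differ_by_at_most_one(self):
        labels = make_folds(468, 10, 1)
        _, counts = np.unique(labels, return_counts=True)
        assert set(counts.tolist()) <= {46, 47}
        assert counts.sum() == 468

    def test_too_few_subjects_is_error(self):
        with pytest.raises(ValueError):
            make_folds(5, 10, 0)


class TestOneSERule:
    def test_single_point_grid_returned(self, rng):
        df = linear_table(rng, n=40)
        X = df[[c for c in df if c != "age"]].to_numpy()
        y = df["age"].to_numpy()
        t = tune_inner(X, y, "enet", [{"alpha": 0.5, "l1_ratio": 0.5}],
                       k_inner=4, repeats=1, seed=0)
        assert t.params == {"alpha": 0.5, "l1_ratio": 0.5}
        assert t.inner_pred.shape == y.shape

    def test_pure_noise_selects_most_regularized(self):
        """On a response unrelated to the features, the one-SE rule should
        land on the most-parsimonious (largest penalty) elastic net."""
        hits = 0
        grid = [{"alpha": a, "l1_ratio": 0.5} for a in (10.0, 0.1, 0.001)]
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (60, 10))
            y = rng.normal(38, 10, 60)
            t = tune_inner(X, y, "enet", grid, k_inner=5, repeats=2, seed=seed)
            if t.params["alpha"] == 10.0:
                hits += 1
        assert hits >= 4

    def test_dominant_point_selected(self, rng):
        """A grid point better by far more than one SE must win even when a
        more parsimonious point exists."""
        df = linear_table(rng, n=80)
        X = df[[c for c in df if c != "age"]].to_numpy()
        y = df["age"].to_numpy()
        grid = [{"alpha": 1000.0, "l1_ratio": 0.5},  # useless: predicts mean
                {"alpha": 0.001, "l1_ratio": 0.5}]
        t = tune_inner(X, y, "enet", grid, k_inner=5, repeats=1, seed=0)
        assert t.params["alpha"] == 0.001


class TestFitStack:
    def test_perfect_model_gets_weight_one(self, rng):
        age = rng.uniform(18, 58, 200)
        preds = {"good": age.copy(),
                 "noise": rng.normal(38, 10, 200),
                 "noise2": rng.normal(38, 10, 200)}
        stack = fit_stack(preds, age, k_ens=5, seed=0)
        w = dict(zip(stack.methods, stack.coef))
        assert w["good"] == pytest.approx(1.0, abs=0.05)
        assert abs(w["noise"]) < 0.05 and abs(w["noise2"]) < 0.05

    def test_identical_predictions_collinear_fallback(self, rng):
        age = rng.uniform(18, 58, 100)
        p = age + rng.normal(0, 5, 100)
        stack = fit_stack({"a": p, "b": p.copy()}, age, k_ens=5, seed=0)
        assert np.isfinite(stack.coef).all()
        assert stack.coef.sum() == pytest.approx(
            np.polyfit(p, age, 1)[0], abs=0.1)

    def test_needs_two_methods(self, rng):
        with pytest.raises(ValueError):
            fit_stack({"only": np.ones(10)}, np.ones(10))


class TestMetrics:
    def test_perfect_prediction(self, rng):
        age = rng.uniform(18, 58, 50)
        m = compute_metrics(age, age)
        assert m == {"r2": 1.0, "mae": 0.0, "rmse": 0.0, "pearson_r": 1.0}

    def test_mean_prediction_r2_zero(self, rng):
        age = rng.uniform(18, 58, 50)
        m = compute_metrics(np.full(50, age.mean()), age)
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset(self, rng):
        age = rng.uniform(18, 58, 50)
        m = compute_metrics(age + 2.0, age)
        assert m["mae"] == pytest.approx(2.0)
        assert m["r2"] < 1.0
        assert m["pearson_r"] == pytest.approx(1.0)

    def test_zero_variance_age_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics(np.ones(10), np.ones(10))


class TestBrainage:
    def test_offsets(self, rng):
        age = rng.uniform(18, 58, 20)
        assert np.allclose(brainage(age, age), 0.0)
        assert np.allclose(brainage(age + 2.0, age), 2.0)


class TestRunNCV:
    def test_noiseless_linear_high_r2(self, rng):
        df = linear_table(rng, n=60)
        cfg = NCVConfig.fast(seed=1, methods=SMALL_METHODS, k_outer=4)
        res = run_ncv(df, cfg)
        assert res.metrics["stack"]["pooled"]["r2"] > 0.95

    def test_each_subject_predicted_exactly_once(self, rng):
        df = linear_table(rng, n=45, noise=3.0)
        cfg = NCVConfig.fast(seed=2, methods=SMALL_METHODS, k_outer=4)
        res = run_ncv(df, cfg)
        assert len(res.predictions) == 45
        assert res.predictions["predicted_age"].notna().all()
        counts = res.predictions.groupby("outer_fold").size()
        assert counts.sum() == 45 and counts.min() >= 11

    def test_no_leakage_on_permuted_ages(self):
        """Mean pooled R^2 over seeds stays within sampling noise of zero."""
        r2s = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            df = linear_table(rng, n=60, noise=3.0)
            df["age"] = rng.permutation(df["age"].values)
            cfg = NCVConfig.fast(seed=seed, methods=SMALL_METHODS, k_outer=4)
            r2s.append(run_ncv(df, cfg).metrics["stack"]["pooled"]["r2"])
        assert -0.15 < np.mean(r2s) < 0.1

    def test_bit_identical_reproducibility(self, rng):
        df = linear_table(rng, n=50, noise=2.0)
        cfg = NCVConfig.fast(seed=9, methods=SMALL_METHODS, k_outer=4)
        a = run_ncv(df, cfg).predictions
        b = run_ncv(df, cfg).predictions
        pd.testing.assert_frame_equal(a, b)

    def test_nan_features_rejected(self, rng):
        df = linear_table(rng, n=30)
        df.iloc[3, 2] = np.nan
        with pytest.raises(ValueError):
            run_ncv(df, NCVConfig.fast(methods=SMALL_METHODS, k_outer=3))

    def test_sex_column_carried_not_modeled(self, rng):
        df = linear_table(rng, n=40, noise=2.0)
        df["sex"] = ["F", "M"] * 20
        cfg = NCVConfig.fast(seed=3, methods=SMALL_METHODS, k_outer=4)
        res = run_ncv(df, cfg)
        assert "sex" not in res.feature_names
        by = metrics_by_group(res.predictions)
        assert set(by) == {"F", "M"}


class TestLearningCurve:
    def test_full_size_equals_direct_run(self, rng):
        df = linear_table(rng, n=40, noise=2.0)
        cfg = NCVConfig.fast(seed=0, methods=SMALL_METHODS, k_outer=4)
        lc = learning_curve(df, cfg, [40], seeds=[5])
        direct = run_ncv(df, NCVConfig.fast(seed=5, methods=SMALL_METHODS,
                                            k_outer=4))
        assert lc.iloc[0]["r2"] == pytest.approx(
            direct.metrics["stack"]["pooled"]["r2"])

    def test_more_samples_help_on_noisy_cohort(self, rng):
        df = linear_table(rng, n=90, noise=6.0)
        cfg = NCVConfig.fast(seed=0, methods=SMALL_METHODS, k_outer=4)
        lc = learning_curve(df, cfg, [20, 90], seeds=[1, 2])
        small = lc[lc["size"] == 20]["r2"].mean()
        large = lc[lc["size"] == 90]["r2"].mean()
        assert large >= small

    def test_too_small_sizes_skipped(self, rng):
        df = linear_table(rng, n=40)
        cfg = NCVConfig.fast(seed=0, methods=SMALL_METHODS, k_outer=4)
        lc = learning_curve(df, cfg, [4], seeds=[0])
        assert len(lc) == 0
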