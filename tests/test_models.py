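"""Regression heads: splitting, fitting, evaluation, attribution."""

import numpy as np
import pandas as pd
import pytest

from deltabh.models import (
    SplitSpec,
    corrected_bh,
    evaluate,
    explain,
    learning_curve,
    split,
    train,
)


class TestSplit:
    def test_sizes(self):
        tr, va, te = split(1000, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (850, 50, 100)

    def test_disjoint_and_exhaustive(self):
        tr, va, te = split(237, SplitSpec(seed=3))
        merged = np.concatenate([tr, va, te])
        assert len(np.unique(merged)) == 237
        assert set(merged) == set(range(237))

    def test_seed_reproducible(self):
        assert all(
            np.array_equal(a, b)
            for a, b in zip(split(500, SplitSpec(seed=9)), split(500, SplitSpec(seed=9)))
        )

    def test_too_small(self):
        with pytest.raises(ValueError):
            split(10, SplitSpec())

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.8, 0.1, 0.2))


def _linear_problem(n=500, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    y = 2.0 * x[:, 0] - 1.0 * x[:, 1] + 0.5 * x[:, 2] + noise * rng.normal(size=n)
    df = pd.DataFrame(x, columns=["pm7.a", "pm7.b", "pm7.c"])
    return df, y


class TestTrain:
    # the smooth-function heads interpolate an exact linear target almost
    # perfectly; the piecewise-constant tree ensemble plateaus at the leaf
    # cell size, i.e. a few percent of the target's spread
    @pytest.mark.parametrize(
        "kind,tol", [("xgb", 0.35), ("gp", 0.1), ("multitask_nn", 0.1)]
    )
    def test_recovers_noiseless_linear_signal(self, kind, tol):
        df, y = _linear_problem(n=500, seed=1)
        tr = np.arange(400)
        te = np.arange(400, 500)
        y_fit = np.column_stack([y, 0.3 * y + 1.0]) if kind == "multitask_nn" else y
        model = train(kind, df.iloc[tr], y_fit[tr] if kind == "multitask_nn" else y[tr],
                      hpo_budget=2, seed=1)
        mae = evaluate(model, df.iloc[te], y[te]).mae
        assert mae < tol, f"{kind} MAE {mae}"

    @pytest.mark.parametrize("kind", ["xgb", "gp"])
    def test_noise_only_target_hits_analytic_mae(self, kind):
        # y ~ N(0, sigma^2) independent of X: best possible MAE is
        # sigma*sqrt(2/pi) for the constant predictor
        rng = np.random.default_rng(4)
        sigma = 1.0
        x = rng.normal(size=(2000, 5))
        y = sigma * rng.normal(size=2000)
        df = pd.DataFrame(x, columns=[f"pm7.v{i}" for i in range(5)])
        model = train(kind, df.iloc[:1500], y[:1500], hpo_budget=4, seed=4, cv_folds=3)
        mae = evaluate(model, df.iloc[1500:], y[1500:]).mae
        floor = sigma * np.sqrt(2 / np.pi)
        assert abs(mae - floor) / floor < 0.15

    def test_degenerate_target_rejected(self):
        df, _ = _linear_problem(n=50)
        with pytest.raises(ValueError, match="zero variance"):
            train("xgb", df, np.ones(50), hpo_budget=0)

    def test_nonfinite_rejected(self):
        df, y = _linear_problem(n=50)
        y = y.copy()
        y[3] = np.inf
        with pytest.raises(ValueError):
            train("gp", df, y)

    def test_unknown_kind(self):
        df, y = _linear_problem(n=50)
        with pytest.raises(ValueError, match="unknown model kind"):
            train("forest", df, y)

    def test_feature_name_mismatch_on_predict(self):
        df, y = _linear_problem()
        model = train("gp", df, y)
        wrong = df.rename(columns={"pm7.a": "pm7.z"})
        with pytest.raises(ValueError, match="feature names"):
            model.predict(wrong)


class TestGP:
    def test_predictive_std_grows_under_extrapolation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(300, 3))
        y = 2 * x[:, 0] - np.sin(2 * x[:, 1]) + 0.1 * rng.normal(size=300)
        df = pd.DataFrame(x, columns=["pm7.a", "pm7.b", "pm7.c"])
        model = train("gp", df, y)
        std_train = model.predict_std(df).mean()
        far = pd.DataFrame(df.to_numpy() + 25.0, columns=df.columns)
        std_far = model.predict_std(far).mean()
        assert std_far > 5 * std_train

    def test_interval_calibration_on_noisy_signal(self):
        # 90% predictive intervals should cover 85-95% of held-out points
        rng = np.random.default_rng(15)
        x = rng.normal(size=(1500, 4))
        y = x[:, 0] + 0.5 * np.tanh(x[:, 1]) + 0.5 * rng.normal(size=1500)
        df = pd.DataFrame(x, columns=[f"pm7.g{i}" for i in range(4)])
        model = train("gp", df.iloc[:1000], y[:1000], seed=15)
        mu = model.predict(df.iloc[1000:])
        sd = model.predict_std(df.iloc[1000:])
        z = 1.6448536269514722  # two-sided 90% normal quantile
        cover = np.mean(np.abs(mu - y[1000:]) <= z * sd)
        assert 0.85 <= cover <= 0.95


class TestCorrectedBH:
    def test_zero_correction_identity(self):
        df, y = _linear_problem(n=100)
        model = train("gp", df, y)

        class Zero:
            kind = "zero"
            feature_names = list(df.columns)

            def predict(self, X):
                return np.zeros(len(X.df if hasattr(X, "df") else X))

        bh = np.linspace(5, 50, 100)
        assert np.allclose(corrected_bh(Zero(), df, bh), bh)

    def test_length_mismatch(self):
        df, y = _linear_problem(n=100)
        model = train("gp", df, y)
        with pytest.raises(ValueError, match="length mismatch"):
            corrected_bh(model, df, np.zeros(7))

    def test_perfect_model_recovers_reference(self):
        df, y = _linear_problem(n=400, seed=2)
        model = train("gp", df, y)
        bh_low = np.full(400, 30.0)
        bh_high = bh_low + y
        out = corrected_bh(model, df, bh_low)
        assert np.abs(out - bh_high).mean() < 0.1


class TestLearningCurve:
    def test_deterministic_with_fixed_seed(self):
        df, y = _linear_problem(n=400, seed=5, noise=0.5)
        t1 = learning_curve("xgb", df, y, sizes=[50, 150], reps=1, seed=5, hpo_budget=0)
        t2 = learning_curve("xgb", df, y, sizes=[50, 150], reps=1, seed=5, hpo_budget=0)
        pd.testing.assert_frame_equal(t1, t2)

    def test_noise_only_curve_is_flat_at_floor(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(1500, 3))
        y = rng.normal(size=1500)
        df = pd.DataFrame(x, columns=["pm7.a", "pm7.b", "pm7.c"])
        t = learning_curve("xgb", df, y, sizes=[100, 400, 1000], reps=2, seed=8, hpo_budget=0)
        floor = np.sqrt(2 / np.pi)
        assert np.all(np.abs(t["mae_mean"] - floor) / floor < 0.2)

    def test_size_exceeding_pool_rejected(self):
        df, y = _linear_problem(n=100)
        with pytest.raises(ValueError):
            learning_curve("xgb", df, y, sizes=[95], reps=1)


class TestExplain:
    def test_ignored_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=(400, 4))
        y = 2.0 * x[:, 0] + x[:, 1]  # features 2, 3 carry no signal
        df = pd.DataFrame(x, columns=["pm7.a", "pm7.b", "pm7.c", "pm7.d"])
        model = train("xgb", df, y, hpo_budget=0, seed=0)
        att = explain(model, df.iloc[:50])
        # any feature the fitted trees never split on gets exactly zero
        gains = model.gain_importances()
        for name in df.columns:
            if gains.get(name, 0.0) == 0.0:
                assert np.abs(att.values[name]).max() == 0.0
        # noise features may pick up spurious splits but stay marginal
        signal_scale = np.abs(att.values["pm7.a"]).mean()
        assert np.abs(att.values["pm7.c"]).mean() < 0.05 * signal_scale
        assert np.abs(att.values["pm7.d"]).mean() < 0.05 * signal_scale

    def test_tree_additivity_machine_precision(self):
        df, y = _linear_problem(n=400, seed=3, noise=0.3)
        model = train("xgb", df, y, hpo_budget=0, seed=3)
        att = explain(model, df.iloc[:80])
        pred = model.predict(df.iloc[:80])
        assert att.check_additivity(pred, tol=1e-9)

    def test_dominant_driver_ranked_first(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=(500, 5))
        y = 5.0 * x[:, 3] + 0.2 * x[:, 0] + 0.05 * rng.normal(size=500)
        df = pd.DataFrame(x, columns=[f"pm7.h{i}" for i in range(5)])
        model = train("xgb", df, y, hpo_budget=0, seed=0)
        att = explain(model, df.iloc[:100])
        assert att.ranking[0] == "pm7.h3"

    def test_sampling_fallback_matches_linear_closed_form(self):
        # for an (approximately) linear model the Shapley value of feature j
        # is slope_j * (x_j - mean_j)
        rng = np.random.default_rng(25)
        x = rng.normal(size=(300, 2))
        y = 3.0 * x[:, 0] - 2.0 * x[:, 1]
        df = pd.DataFrame(x, columns=["pm7.a", "pm7.b"])
        model = train("gp", df, y, seed=0)
        att = explain(model, df.iloc[:20], n_permutations=16, seed=0)
        # the fallback's background is the mean of the explained rows
        expected_a = 3.0 * (x[:20, 0] - x[:20, 0].mean())
        assert np.max(np.abs(att.values["pm7.a"] - expected_a)) < 0.15


def test_seed_reproducibility_end_to_end():
    df, y = _linear_problem(n=300, seed=6, noise=0.5)
    m1 = train("xgb", df, y, hpo_budget=2, seed=6)
    m2 = train("xgb", df, y, hpo_budget=2, seed=6)
    assert np.array_equal(m1.predict(df), m2.predict(df))
    g1 = train("gp", df, y, seed=6)
    g2 = train("gp", df, y, seed=6)
    assert np.array_equal(g1.predict(df), g2.predict(df))
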