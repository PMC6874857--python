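import numpy as np
import pandas as pd
import pytest

from ecointegrity import (
    SelectionConfig,
    aicc,
    cross_validate,
    fit_ols,
    r_squared,
    select_best,
)
from ecointegrity.modeling import (
    enumerate_candidates,
    predict_surface,
    predict_table,
    scale_predictors,
)
from ecointegrity.synthetic import sigma_for_r2

from oracles import gaussian_loglik, normal_equations, pearson_r2, textbook_aicc


def random_table(rng, n, names):
    return pd.DataFrame(rng.uniform(0, 1, (n, len(names))), columns=list(names))


class TestScaling:
    def test_minmax_example(self):
        scaled, record = scale_predictors(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        np.testing.assert_allclose(scaled["a"], [0.0, 0.5, 1.0])
        assert record.bounds["a"] == (2.0, 6.0)

    def test_unit_column_unchanged(self):
        df = pd.DataFrame({"a": [0.0, 0.3, 1.0]})
        scaled, _ = scale_predictors(df)
        np.testing.assert_allclose(scaled["a"], df["a"])

    def test_projection_onto_new_value(self):
        _, record = scale_predictors(pd.DataFrame({"a": [2.0, 4.0, 6.0]}))
        assert record.apply_value("a", 5.0) == pytest.approx(0.75)

    def test_constant_column_warns_scales_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            scaled, _ = scale_predictors(pd.DataFrame({"a": [3.0, 3.0]}))
        np.testing.assert_array_equal(scaled["a"], [0.0, 0.0])


class TestFitOls:
    def test_exact_line_recovered(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 0.8 - 0.5 * x
        fit = fit_ols(y, pd.DataFrame({"x": x}), ["x"])
        assert fit.intercept == pytest.approx(0.8, abs=1e-12)
        assert fit.coefficients["x"] == pytest.approx(-0.5, abs=1e-12)
        assert fit.r2_insample == pytest.approx(1.0)

    def test_intercept_only_is_mean(self, rng):
        y = rng.normal(size=25)
        fit = fit_ols(y, pd.DataFrame(index=range(25)), [])
        assert fit.intercept == pytest.approx(y.mean())

    def test_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        fit = fit_ols(y, df)
        expected = normal_equations(y, X)
        got = np.concatenate([[fit.intercept], [fit.coefficients[c] for c in "abc"]])
        np.testing.assert_allclose(got, expected, atol=1e-10)
        assert fit.loglik == pytest.approx(gaussian_loglik(y, X), abs=1e-9)

    def test_rank_deficiency_names_columns(self, rng):
        a = rng.normal(size=20)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ols(rng.normal(size=20), df)

    def test_n_too_small_rejected(self, rng):
        df = random_table(rng, 3, "abc")
        with pytest.raises(ValueError, match="too small"):
            fit_ols(np.zeros(3), df)


class TestAicc:
    def test_closed_form_example(self):
        assert aicc(-10.0, 20, 3) == pytest.approx(27.5)

    def test_large_n_limit_equals_aic(self):
        assert aicc(-50.0, 10**6, 3) - (100 + 6) < 1e-3

    def test_textbook_formula_oracle(self, rng):
        for _ in range(50):
            ll = rng.uniform(-200, 0)
            n = int(rng.integers(10, 500))
            k = int(rng.integers(1, 6))
            assert aicc(ll, n, k) == pytest.approx(textbook_aicc(ll, n, k), rel=1e-12)

    def test_inadmissible_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 4)


class TestEnumerate:
    def test_counts_without_collinearity(self):
        corr = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        got = enumerate_candidates(list("abcde"), SelectionConfig(max_terms=2), corr)
        assert len(got) == 16  # 1 + 5 + 10
        assert got[0] == ()

    def test_collinear_pair_excluded(self):
        corr = pd.DataFrame(
            [[1.0, 0.9], [0.9, 1.0]], index=["x1", "x2"], columns=["x1", "x2"]
        )
        got = enumerate_candidates(["x1", "x2"], SelectionConfig(max_terms=2), corr)
        assert got == [(), ("x1",), ("x2",)]

    def test_threshold_is_strict(self):
        corr = pd.DataFrame(
            [[1.0, 0.7], [0.7, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        got = enumerate_candidates(["a", "b"], SelectionConfig(max_terms=2), corr)
        assert ("a", "b") in got  # |r| == 0.7 is not "> 0.7"

    def test_exhaustive_filter_oracle(self, rng):
        import itertools

        names = list("abcdefg")
        r = rng.uniform(-1, 1, (7, 7))
        corr = (r + r.T) / 2
        np.fill_diagonal(corr, 1.0)
        config = SelectionConfig(max_terms=3)
        got = set(
            enumerate_candidates(names, config, pd.DataFrame(corr, index=names, columns=names))
        )
        expected = set()
        for size in range(4):
            for combo in itertools.combinations(names, size):
                idx = [names.index(c) for c in combo]
                if all(
                    abs(corr[i, j]) <= 0.7
                    for i, j in itertools.combinations(idx, 2)
                ):
                    expected.add(combo)
        assert got == expected

    def test_deterministic_ordering(self):
        corr = pd.DataFrame(np.eye(3), index=list("cab"), columns=list("cab"))
        got = enumerate_candidates(list("cab"), SelectionConfig(max_terms=2), corr)
        assert got == [
            (), ("a",), ("b",), ("c",),
            ("a", "b"), ("a", "c"), ("b", "c"),
        ]


class TestSelectBest:
    def test_pure_signal_selects_true_predictor(self, rng):
        X = random_table(rng, 50, ["x1", "d1", "d2", "d3", "d4"])
        y = 0.3 + 0.6 * X["x1"].to_numpy()
        best, table = select_best(y, X, SelectionConfig(max_terms=3))
        assert best.subset == ("x1",)

    def test_selected_aicc_is_table_minimum(self, rng):
        X = random_table(rng, 60, list("abcd"))
        y = rng.normal(size=60)
        best, table = select_best(y, X, SelectionConfig(max_terms=2))
        assert best.aicc == pytest.approx(table["aicc"].min())

    def test_pure_noise_prefers_intercept_only(self):
        wins = 0
        runs = 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            X = random_table(rng, 200, list("ab"))
            y = rng.normal(size=200)
            best, _ = select_best(y, X, SelectionConfig(max_terms=2))
            wins += best.subset == ()
        assert wins > runs / 2

    def test_no_selected_model_contains_collinear_pair(self, rng):
        a = rng.uniform(0, 1, 80)
        X = pd.DataFrame(
            {"a": a, "b": a + rng.normal(0, 0.05, 80), "c": rng.uniform(0, 1, 80)}
        )
        assert abs(X.corr().loc["a", "b"]) > 0.7
        y = 0.2 + a + rng.normal(0, 0.1, 80)
        best, table = select_best(y, X, SelectionConfig(max_terms=3))
        assert not {"a", "b"} <= set(best.subset)
        assert not table["subset"].str.contains(r"a\+b").any()

    def test_constant_columns_dropped_with_warning(self, rng):
        X = random_table(rng, 40, ["a"])
        X["const"] = 1.0
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="constant"):
            best, _ = select_best(y, X, SelectionConfig(max_terms=2))
        assert "const" not in best.subset


class TestRSquared:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=10)
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_constant_prediction_zero(self, rng):
        assert r_squared(rng.normal(size=10), np.full(10, 0.5)) == 0.0

    def test_covariance_formula_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            assert r_squared(a, b) == pytest.approx(pearson_r2(a, b), abs=1e-12)

    def test_ss_variant(self, rng):
        y = rng.normal(size=30)
        pred = y + rng.normal(0, 0.5, 30)
        expected = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r_squared(y, pred, method="ss") == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCrossValidate:
    def test_noiseless_model_scores_one(self, rng):
        X = random_table(rng, 70, ["x"])
        y = 0.7 - 0.4 * X["x"].to_numpy()
        cv = cross_validate(y, X, ["x"], k=7, repeats=5, seed=0)
        assert cv.mean_r2 == pytest.approx(1.0)

    def test_fold_sizes_equal_at_140(self, rng):
        n, k = 140, 7
        perm = np.random.default_rng(0).permutation(n)
        folds = np.array_split(perm, k)
        assert all(len(f) == 20 for f in folds)

    def test_near_equal_folds_at_29(self):
        folds = np.array_split(np.arange(29), 7)
        sizes = sorted(len(f) for f in folds)
        assert max(sizes) - min(sizes) == 1
        assert sum(sizes) == 29

    def test_deterministic_under_seed(self, rng):
        X = random_table(rng, 60, ["x", "z"])
        y = rng.normal(size=60)
        a = cross_validate(y, X, ["x"], k=5, repeats=3, seed=42)
        b = cross_validate(y, X, ["x"], k=5, repeats=3, seed=42)
        np.testing.assert_array_equal(a.scores, b.scores)
        c = cross_validate(y, X, ["x"], k=5, repeats=3, seed=43)
        assert not np.array_equal(a.scores, c.scores)

    def test_mean_sd_consistent_with_scores(self, rng):
        X = random_table(rng, 60, ["x"])
        y = 0.5 * X["x"].to_numpy() + rng.normal(0, 0.2, 60)
        cv = cross_validate(y, X, ["x"], k=5, repeats=4, seed=1)
        assert cv.scores.shape == (4, 5)
        assert cv.mean_r2 == pytest.approx(cv.scores.mean())
        assert cv.sd_r2 == pytest.approx(cv.scores.std(ddof=1))

    def test_analytic_signal_fraction_recovered(self, rng):
        n = 1000
        X = random_table(rng, n, ["a", "b"])
        beta = np.array([0.5, -0.3])
        eta = 0.5 + X.to_numpy() @ beta
        sigma = sigma_for_r2(eta, 0.5)
        y = eta + rng.normal(0, sigma, n)
        cv = cross_validate(y, X, ["a", "b"], k=7, repeats=20, seed=3)
        assert 0.45 <= cv.mean_r2 <= 0.55

    def test_too_small_n_rejected(self, rng):
        X = random_table(rng, 10, ["x"])
        with pytest.raises(ValueError, match="too small"):
            cross_validate(np.zeros(10), X, ["x"], k=7)


class TestPredict:
    def test_intercept_only_uniform_surface(self):
        from ecointegrity.modeling import FitResult

        fit = FitResult(
            subset=(), intercept=0.7, coefficients={}, coefficient_se={},
            intercept_se=0.0, sigma2_mle=0.0, loglik=0.0, aicc=0.0,
            r2_insample=0.0, n=10, k_params=2,
        )
        surface, clamped = predict_surface(fit, {"any": np.zeros((5, 8))})
        np.testing.assert_array_equal(surface, np.full((5, 8), 0.7))
        assert clamped == 0

    def test_zero_threat_pixels_predict_intercept(self, rng):
        X = pd.DataFrame({"t": np.concatenate([[0.0] * 5, rng.uniform(0, 1, 45)])})
        y = 0.74 - 0.2 * X["t"].to_numpy() + rng.normal(0, 0.01, 50)
        fit = fit_ols(y, X, ["t"])
        surface, _ = predict_surface(fit, {"t": np.zeros((3, 3))})
        np.testing.assert_allclose(surface, fit.intercept)

    def test_dot_product_oracle(self, rng):
        X = random_table(rng, 100, ["a", "b"])
        y = 0.6 - 0.3 * X["a"] + 0.2 * X["b"] + rng.normal(0, 0.05, 100)
        fit = fit_ols(y.to_numpy(), X)
        rasters = {
            "a": rng.uniform(0, 1, (30, 30)),
            "b": rng.uniform(0, 1, (30, 30)),
        }
        surface, _ = predict_surface(fit, rasters)
        for r in range(30):
            for c in range(30):
                expected = (
                    fit.intercept
                    + fit.coefficients["a"] * rasters["a"][r, c]
                    + fit.coefficients["b"] * rasters["b"][r, c]
                )
                assert surface[r, c] == pytest.approx(np.clip(expected, 0, 1), abs=1e-12)

    def test_missing_raster_rejected(self, rng):
        X = random_table(rng, 30, ["a"])
        fit = fit_ols(rng.normal(size=30), X)
        with pytest.raises(KeyError, match="missing"):
            predict_surface(fit, {"other": np.zeros((2, 2))})

    def test_clamp_count_reported(self, rng):
        X = random_table(rng, 30, ["a"])
        y = 2.0 + X["a"].to_numpy()  # predictions way above 1
        fit = fit_ols(y, X, ["a"])
        surface, clamped = predict_surface(fit, {"a": rng.uniform(0, 1, (4, 4))})
        assert clamped == 16
        assert np.all(surface == 1.0)

    def test_predict_table_scaling_record(self, rng):
        raw = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        scaled, record = scale_predictors(raw)
        y = np.array([0.9, 0.5, 0.1])
        fit = fit_ols(y, scaled, ["a"])
        pred, _ = predict_table(fit, raw, record)
        np.testing.assert_allclose(pred, y, atol=1e-12)


class TestParameterRecoveryMini:
    def test_true_predictors_recovered(self, rng):
        # compact version of the recovery property; the full 50-replicate
        # run lives in the acceptance suite
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = random_table(r, 140, ["t1", "t2", "t3", "e1", "e2", "d1", "d2"])
            beta = {"t1": -0.3, "t2": -0.25, "t3": 0.2, "e1": -0.25, "e2": 0.3}
            eta = 0.7 + sum(b * X[c].to_numpy() for c, b in beta.items())
            sigma = sigma_for_r2(eta, 0.5)
            y = eta + r.normal(0, sigma, 140)
            best, _ = select_best(y, X, SelectionConfig(max_terms=7))
            hits += set(beta) <= set(best.subset)
        assert hits >= 9
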