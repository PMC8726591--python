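"""Weighted least squares, the model family, AICc, the equal-effects test,
calibration, and prediction-based classification."""

import numpy as np
import pandas as pd
import pytest

import quantiptw as q
from quantiptw.weighting import WeightSet


def normal_equations_oracle(y, X, w):
    """Independent WLS solver: beta = (X'WX)^-1 X'Wy with model-based
    covariance sigma2 (X'WX)^-1."""
    X1 = np.column_stack([np.ones(len(y)), X])
    W = np.diag(w)
    xtwx = X1.T @ W @ X1
    beta = np.linalg.solve(xtwx, X1.T @ W @ y)
    resid = y - X1 @ beta
    sigma2 = (resid * w * resid).sum() / (len(y) - X1.shape[1])
    cov = sigma2 * np.linalg.inv(xtwx)
    return beta, np.sqrt(np.diag(cov))


class TestFitWls:
    def test_exact_fit_zero_residuals(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [0.0, 1, 0, 1]})
        y = 2 + 3 * X["a"] - 1.5 * X["b"]
        fit = q.fit_wls(y, X)
        np.testing.assert_allclose(
            fit.params[["const", "a", "b"]], [2, 3, -1.5], atol=1e-10
        )

    def test_matches_normal_equations_oracle(self, rng):
        """100 random 50x3 weighted problems against an independently
        coded normal-equations solver, to 1e-8."""
        for _ in range(100):
            X = rng.normal(size=(50, 3))
            y = rng.normal(size=50)
            w = rng.random(50) + 0.1
            fit = q.fit_wls(y, pd.DataFrame(X, columns=list("abc")), w)
            beta, se = normal_equations_oracle(y, X, w)
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)
            np.testing.assert_allclose(fit.ses.to_numpy(), se, atol=1e-8)

    def test_row_duplication_equals_double_weight(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        Xd = np.vstack([X, X[:1]])
        yd = np.append(y, y[0])
        w = np.ones(30)
        w[0] = 2.0
        f_dup = q.fit_wls(yd, pd.DataFrame(Xd, columns=["a", "b"]))
        f_wtd = q.fit_wls(y, pd.DataFrame(X, columns=["a", "b"]), w)
        np.testing.assert_allclose(
            f_dup.params.to_numpy(), f_wtd.params.to_numpy(), atol=1e-10
        )

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": 3 * x})
        with pytest.raises(ValueError, match="b"):
            q.fit_wls(rng.normal(size=40), X)

    def test_ci_halfwidth_consistent_with_t(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=25)})
        fit = q.fit_wls(rng.normal(size=25), X)
        from scipy import stats

        half = stats.t.ppf(0.975, fit.df_resid) * fit.ses["a"]
        assert fit.cis.loc["a", "hi"] - fit.params["a"] == pytest.approx(half)


class TestAicc:
    def test_penalty_arithmetic(self):
        assert q.aicc(0.0, 3, 10) == pytest.approx(6 + 4.0)

    def test_vanishes_at_large_n(self):
        gaps = [q.aicc(0.0, 3, n) - 6.0 for n in (20, 100, 1000, 100_000)]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-3

    def test_k_zero_is_plain_aic(self):
        assert q.aicc(-10.0, 0, 50) == pytest.approx(20.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="AICc"):
            q.aicc(0.0, 5, 6)

    def test_aicc_exceeds_aic_on_fits(self, vocab_cohort):
        table, _ = vocab_cohort
        fit = q.fit_wls(table["y"], table[["z1", "z2"]])
        assert fit.aicc > fit.aic


class TestModelSuite:
    def test_constant_truth_prefers_constant_model(self, rng):
        """Exact equal effects, tiny noise: the constant model recovers
        delta and beats the differing model on AICc."""
        n = 64
        z1 = rng.normal(400, 120, n)
        z2 = 0.5 * z1 + rng.normal(200, 80, n)
        delta = 0.021
        y = 90 + delta * (z1 + z2) + rng.normal(0, 1e-6, n)
        table = pd.DataFrame({"z1": z1, "z2": z2, "y": y})
        suite = q.fit_model_suite(table, "z1", "z2", "y", WeightSet.unit(n))
        cum = suite["constant"].predictors[0]
        assert suite["constant"].params[cum] == pytest.approx(delta, abs=1e-9)
        assert suite["constant"].aicc < suite["differing"].aicc

    def test_later_only_truth_recovery(self, rng):
        n = 2000
        z1 = rng.normal(400, 120, n)
        z2 = 0.5 * z1 + rng.normal(200, 80, n)
        y = 90 + 0.04 * z2 + rng.normal(0, 5, n)
        table = pd.DataFrame({"z1": z1, "z2": z2, "y": y})
        suite = q.fit_model_suite(table, "z1", "z2", "y", WeightSet.unit(n))
        fit = suite["later_strong"]
        assert abs(fit.params["z2"] - 0.04) < 3 * fit.ses["z2"]

    def test_bookkeeping_consistent(self, vocab_cohort):
        table, _ = vocab_cohort
        ws = q.iptw_weights(
            table, "z1", "z2", ["parent_verbal_iq", "income"], ["z1", "x1"], k=8
        )
        suite = q.fit_model_suite(table, "z1", "z2", "y", ws)
        assert set(suite) == {
            "differing", "constant", "earlier_only_weighted_baseline",
            "earlier_strong", "later_strong",
        }
        assert len({fit.n for fit in suite.values()}) == 1
        assert all(
            fit.weights_provenance == ws.model_provenance for fit in suite.values()
        )


class TestEqualEffects:
    def test_symmetric_data_gives_zero_difference(self):
        # every (a, b) row has a mirrored (b, a) row with the same outcome,
        # so the fitted roles of z1 and z2 are exactly exchangeable
        z1 = np.array([1.0, 2.0, 3.0, 1.0, 5.0, 4.0])
        z2 = np.array([2.0, 1.0, 1.0, 3.0, 4.0, 5.0])
        y = np.array([3.1, 3.1, 4.0, 4.0, 9.2, 9.2])
        table = pd.DataFrame({"z1": z1, "z2": z2, "y": y})
        fit = q.fit_wls(y, table[["z1", "z2"]], model_kind="differing")
        res = q.test_equal_effects(fit)
        assert res["estimate"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_wald(self, rng):
        X = pd.DataFrame({"z1": rng.normal(size=80), "z2": rng.normal(size=80)})
        y = 0.3 * X["z1"] - 0.2 * X["z2"] + rng.normal(size=80)
        fit = q.fit_wls(y, X, model_kind="differing")
        res = q.test_equal_effects(fit)
        c = np.array([0.0, -1.0, 1.0])  # const, z1, z2
        V = fit.cov_params.to_numpy()
        est = c @ fit.params.to_numpy()
        se = np.sqrt(c @ V @ c)
        assert res["estimate"] == pytest.approx(est, abs=1e-10)
        assert res["se"] == pytest.approx(se, abs=1e-10)

    def test_reparameterized_refit_agrees(self, rng):
        """Fitting y ~ (z1+z2)/2 + (z2-z1) reads the difference directly;
        it must agree with the Wald contrast."""
        X = pd.DataFrame({"z1": rng.normal(size=60), "z2": rng.normal(size=60)})
        y = 0.5 * X["z1"] + 0.1 * X["z2"] + rng.normal(size=60)
        fit = q.fit_wls(y, X, model_kind="differing")
        res = q.test_equal_effects(fit)
        Xr = pd.DataFrame(
            {"s": (X["z1"] + X["z2"]) / 2, "d": (X["z2"] - X["z1"]) / 2}
        )
        refit = q.fit_wls(y, Xr)
        assert refit.params["d"] == pytest.approx(res["estimate"], abs=1e-10)
        assert refit.ses["d"] == pytest.approx(res["se"], abs=1e-10)

    def test_syntax_like_difference_recovery(self):
        """Differing truth (-0.24, +0.22): the estimated difference sits
        within 3 MC SEs of 0.46."""
        truth = q.truth_syntax(seed=13).replace(n=2000, miss_rates={}, sigma_y=0.5)
        table, _ = q.generate_cohort(truth)
        ws = q.iptw_weights(
            table, "z1", "z2",
            ["parent_verbal_iq", "birth_order", "child_word_types_14"],
            ["z1", "x1", "parent_verbal_iq", "education", "child_gender"],
            k=8,
        )
        fit = q.fit_wls(table["y"], table[["z1", "z2"]], ws.w, model_kind="differing")
        res = q.test_equal_effects(fit)
        want = truth.msm_delta2 - truth.msm_delta1
        assert res["estimate"] == pytest.approx(want, abs=3 * res["se"])


class TestCalibration:
    def test_identical_profiles_zero_difference(self, vocab_cohort):
        table, _ = vocab_cohort
        fit = q.fit_wls(table["y"], table[["z1", "z2"]], model_kind="differing")
        out = q.calibrate_effect(fit, (400, 450), (400, 450), sd_outcome=13.39)
        assert out["difference"] == 0.0

    def test_constant_model_profile_arithmetic(self):
        """A constant-effects fit with slope 0.021 maps the cumulative gap
        474+540-336-362 = 316 word types to 0.021*316 = 6.64 points."""
        z = np.linspace(300, 1100, 40)
        y = 50 + 0.021 * z
        fit = q.fit_wls(y, pd.DataFrame({"cum": z}), model_kind="constant")
        out = q.calibrate_effect(fit, (336, 362), (474, 540), sd_outcome=13.39)
        assert out["difference"] == pytest.approx(0.021 * 316, abs=1e-8)
        assert out["standardized_difference"] == pytest.approx(
            0.021 * 316 / 13.39, abs=1e-8
        )

    def test_standardized_difference_helper(self):
        assert q.standardized_difference(109.6, 115.7, 13.39) == pytest.approx(
            0.4556, abs=1e-4
        )


class TestClassifyPredictions:
    def test_counts_16_32_16(self, vocab_cohort):
        table, _ = vocab_cohort
        fit = q.fit_wls(
            table["y"],
            pd.DataFrame({"cum": table["z1"] + table["z2"]}),
            model_kind="constant",
        )
        out = q.classify_predictions(fit, table, "z1", "z2", n_top=16, n_bottom=16)
        counts = out["label"].value_counts()
        assert counts["high"] == 16 and counts["low"] == 16 and counts["mid"] == 32

    def test_constant_model_ranks_by_cumulative_exposure(self, vocab_cohort):
        table, _ = vocab_cohort
        fit = q.fit_wls(
            table["y"],
            pd.DataFrame({"cum": table["z1"] + table["z2"]}),
            model_kind="constant",
        )
        out = q.classify_predictions(fit, table, "z1", "z2")
        cum = out["z1"] + out["z2"]
        assert cum[out["label"] == "high"].min() >= cum[out["label"] == "mid"].max() - 1e-9

    def test_too_many_labels_rejected(self, vocab_cohort):
        table, _ = vocab_cohort
        fit = q.fit_wls(table["y"], table[["z1", "z2"]], model_kind="differing")
        with pytest.raises(ValueError, match="exceeds"):
            q.classify_predictions(fit, table, "z1", "z2", n_top=40, n_bottom=40)

    def test_degenerate_ties_use_stable_order(self):
        table = pd.DataFrame({"z1": [1.0] * 12, "z2": [2.0] * 12, "y": [0.0] * 12})
        a = np.arange(12.0)
        fit = q.fit_wls(
            pd.Series(a + a**2),
            pd.DataFrame({"z1": a, "z2": a**2}),
            model_kind="differing",
        )
        out = q.classify_predictions(fit, table, "z1", "z2", n_top=3, n_bottom=3)
        assert list(out["label"][:3]) == ["low"] * 3
        assert list(out["label"][-3:]) == ["high"] * 3
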