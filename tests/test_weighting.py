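"""Quantile binning, the ordinal exposure model, and stabilized weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import quantiptw as q
from quantiptw.weighting import OrdinalExposureModel

from conftest import newton_logistic


class TestAssignQuantileBins:
    def test_one_value_per_bin(self):
        b = q.assign_quantile_bins([1, 2, 3, 4, 5, 6, 7, 8], k=8)
        np.testing.assert_array_equal(b.assignment, np.arange(1, 9))

    def test_rank_oracle(self):
        """Bins must agree with ceil(rank * k / n) for distinct values."""
        x = np.array([10, 20, 30, 40, 50, 60, 70, 80], dtype=float)
        b = q.assign_quantile_bins(x, k=4)
        np.testing.assert_array_equal(b.assignment, [1, 1, 2, 2, 3, 3, 4, 4])
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, k = 64, 8
            x = rng.normal(size=n)
            b = q.assign_quantile_bins(x, k)
            ranks = np.argsort(np.argsort(x)) + 1
            oracle = np.ceil(ranks * k / n).astype(int)
            np.testing.assert_array_equal(b.assignment.astype(int), oracle)

    def test_equal_split_64(self):
        rng = np.random.default_rng(0)
        b = q.assign_quantile_bins(rng.normal(size=64), k=8)
        counts = np.bincount(b.assignment.astype(int))[1:]
        assert (counts == 8).all()

    def test_boundary_value_goes_low(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        b = q.assign_quantile_bins(x, k=2)
        # boundary is the median 2.5; 2.0 < 2.5 stays in bin 1
        np.testing.assert_array_equal(b.assignment, [1, 1, 2, 2])

    def test_errors(self):
        with pytest.raises(ValueError, match="k"):
            q.assign_quantile_bins([1, 2, 3, 4], k=1)
        with pytest.raises(ValueError, match="at least k"):
            q.assign_quantile_bins([1, 2, 3], k=4)
        with pytest.raises(ValueError, match="lower k"):
            q.assign_quantile_bins([1.0] * 30 + [2.0, 3.0], k=4)


class TestFitCumulativeLogit:
    def test_intercept_only_balanced(self):
        m = q.fit_cumulative_logit(np.array([1] * 5 + [2] * 5))
        np.testing.assert_allclose(m.cutpoints, [0.0], atol=1e-12)

    def test_intercept_only_unbalanced(self):
        m = q.fit_cumulative_logit(np.array([1] * 6 + [2] * 2))
        np.testing.assert_allclose(m.cutpoints, [np.log(3)], atol=1e-12)

    def test_k2_equals_logistic_regression(self, rng):
        """At K=2 the proportional-odds model is a plain logistic
        regression of bin-2 membership; compare against an independently
        coded Newton MLE."""
        n = 300
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + 0.8 * x)))
        bins = (rng.random(n) < p) + 1
        m = q.fit_cumulative_logit(bins, pd.DataFrame({"x": x}))
        beta = newton_logistic(x[:, None], (bins == 2).astype(float))
        assert m.coefficients[0] == pytest.approx(beta[1], abs=1e-5)
        assert m.cutpoints[0] == pytest.approx(-beta[0], abs=1e-5)

    def test_centering_invariance(self, rng):
        n = 400
        x = rng.normal(size=n, loc=50, scale=5)
        bins = q.assign_quantile_bins(rng.normal(size=n) + 0.1 * x, k=4).assignment
        m_raw = q.fit_cumulative_logit(bins, pd.DataFrame({"x": x}))
        m_ctr = q.fit_cumulative_logit(bins, pd.DataFrame({"x": x - x.mean()}))
        assert m_raw.coefficients[0] == pytest.approx(m_ctr.coefficients[0], abs=1e-4)
        shift = m_raw.coefficients[0] * x.mean()
        np.testing.assert_allclose(m_raw.cutpoints, m_ctr.cutpoints + shift, atol=1e-3)

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(size=100)
        bins = (x > 0) + 1
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            q.fit_cumulative_logit(bins, X)

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            q.fit_cumulative_logit(np.ones(20))


class TestBinProbabilities:
    def test_intercept_only_equal_counts(self):
        m = q.fit_cumulative_logit(np.repeat([1, 2, 3, 4], 5))
        p = q.bin_probabilities(m, pd.DataFrame(index=range(3)))
        np.testing.assert_allclose(p, np.full((3, 4), 0.25), atol=1e-10)

    def test_logistic_arithmetic(self):
        m = OrdinalExposureModel(
            cutpoints=np.array([-1.0, 1.0]), coefficients=np.empty(0),
            covariate_names=(), converged=True, loglik=0.0,
        )
        p = q.bin_probabilities(m, [[0.0]])
        np.testing.assert_allclose(p[0], [0.26894142, 0.46211716, 0.26894142], atol=1e-7)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(0, 10_000))
    def test_simplex_conservation(self, k, seed):
        """Rows of the probability matrix are strictly positive and sum
        to 1 for arbitrary cutpoints and linear predictors."""
        rng = np.random.default_rng(seed)
        cut = np.sort(rng.normal(size=k - 1, scale=2))
        cut += np.arange(k - 1) * 1e-6  # strict monotonicity under ties
        beta = rng.normal(size=2)
        m = OrdinalExposureModel(
            cutpoints=cut, coefficients=beta, covariate_names=("a", "b"),
            converged=True, loglik=0.0,
        )
        X = pd.DataFrame(rng.normal(size=(20, 2), scale=3), columns=["a", "b"])
        p = q.bin_probabilities(m, X)
        assert (p > 0).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_name_mismatch(self):
        m = OrdinalExposureModel(
            cutpoints=np.array([0.0]), coefficients=np.array([1.0]),
            covariate_names=("income",), converged=True, loglik=0.0,
        )
        with pytest.raises(ValueError, match="income"):
            q.bin_probabilities(m, pd.DataFrame({"education": [1.0]}))


class TestStabilizedWeights:
    def test_no_confounding_gives_unit_weights(self):
        p_marg = np.array([0.5, 0.5])
        p_cond = np.tile(p_marg, (4, 1))
        w = q.stabilized_weights(p_marg, p_cond, [1, 2, 1, 2])
        np.testing.assert_allclose(w, 1.0)

    def test_hand_arithmetic(self):
        p_marg = np.array([0.5, 0.5])
        p_cond = np.array([[0.8, 0.2]])
        assert q.stabilized_weights(p_marg, p_cond, [1])[0] == pytest.approx(0.625)
        assert q.stabilized_weights(p_marg, p_cond, [2])[0] == pytest.approx(2.5)

    def test_positivity_floor(self):
        p_cond = np.array([[1 - 1e-9, 1e-9]])
        with pytest.raises(ValueError, match="positivity"):
            q.stabilized_weights(np.array([0.5, 0.5]), p_cond, [2])


class TestCombineWeights:
    def test_identity_and_cancellation(self):
        ws = q.combine_weights([2.0, 0.5], [1.0, 1.0])
        np.testing.assert_allclose(ws.w, [2.0, 0.5])
        ws = q.combine_weights([2.0, 0.5], [0.5, 2.0])
        np.testing.assert_allclose(ws.w, [1.0, 1.0])

    def test_winsorization(self):
        ws = q.combine_weights([1.0, 1.0, 1.0, 10.0], np.ones(4), truncation=(0, 75))
        np.testing.assert_allclose(ws.w, [1.0, 1.0, 1.0, 1.0])
        assert ws.truncation == (0, 75)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            q.combine_weights([1.0, -1.0], [1.0, 1.0])


class TestWeightingPipeline:
    def test_null_confounding_weights_near_one(self):
        """When exposure is independent of covariates the stabilized
        weights hover around 1 and barely move any association.  Run at
        n=8000: weight-estimation noise alone perturbs correlations by
        ~0.03 at n=2000, an order-1/sqrt(n) artifact of fitting a null
        exposure model, so the 0.02 tolerance needs the larger cohort."""
        table, _ = q.generate_cohort(q.truth_null_confounding(n=8000, seed=4))
        w, _, _ = q.exposure_weights(
            table, "z1", ["parent_verbal_iq", "income"], k=8
        )
        assert 0.95 <= w.mean() <= 1.05
        for cov in ("parent_verbal_iq", "income"):
            raw = q.weighted_correlation(table["z1"], table[cov], np.ones(len(table)))
            wtd = q.weighted_correlation(table["z1"], table[cov], w)
            assert abs(wtd - raw) < 0.02

    def test_k2_pathway_matches_independent_logistic(self, big_confounded_cohort):
        """bins -> ordinal fit -> stabilized weights at K=2 reproduces
        weights computed from an independently coded logistic MLE."""
        table, _ = big_confounded_cohort
        covs = ["parent_verbal_iq", "income"]
        w, model, binning = q.exposure_weights(table, "z1", covs, k=2)

        X = table[covs].to_numpy()
        yy = (binning.assignment == 2).astype(float)
        beta = newton_logistic(X, yy)
        p2 = 1 / (1 + np.exp(-(beta[0] + X @ beta[1:])))
        p_obs = np.where(yy == 1, p2, 1 - p2)
        marg = np.where(yy == 1, yy.mean(), 1 - yy.mean())
        np.testing.assert_allclose(w, marg / p_obs, atol=1e-6)
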