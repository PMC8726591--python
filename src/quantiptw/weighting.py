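"""Quantile-binned inverse-probability-of-treatment weighting.

For a continuous exposure there is no single "probability of treatment".
The quantile-binning approach discretizes the exposure into K equal-
frequency bins, models bin membership with a proportional-odds
(cumulative-logit) regression on confounders, and weights each subject by

    w_i = P(bin = b_i) / P(bin = b_i | covariates_i)

(the stabilized form; the unstabilized form drops the numerator).  Subjects
whose covariates made their observed exposure level unlikely are
up-weighted, so in the weighted sample exposure level is approximately
independent of the covariates — mimicking randomization.  With two exposure
occasions the two stabilized weights are multiplied, accounting for the
propensity to receive the observed *sequence* of exposures.

The proportional-odds fit is delegated to
:class:`statsmodels.miscmodels.ordinal_model.OrderedModel`
(``P(bin <= j | x) = logistic(theta_j - x' beta)``); intercept-only models
use the closed form ``theta_j = logit(cumulative frequency)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "QuantileBinning",
    "OrdinalExposureModel",
    "WeightSet",
    "assign_quantile_bins",
    "fit_cumulative_logit",
    "bin_probabilities",
    "stabilized_weights",
    "combine_weights",
    "exposure_weights",
    "iptw_weights",
]

PROBABILITY_FLOOR = 1e-6


@dataclass(frozen=True)
class QuantileBinning:
    k: int
    boundaries: np.ndarray  # K-1 cut values, nondecreasing
    assignment: np.ndarray  # labels in 1..K (float NaN where exposure missing)


@dataclass(frozen=True)
class OrdinalExposureModel:
    cutpoints: np.ndarray  # theta_1 < ... < theta_{K-1}, logit scale
    coefficients: np.ndarray  # beta, one per covariate
    covariate_names: tuple[str, ...]
    converged: bool
    loglik: float

    @property
    def k(self) -> int:
        return len(self.cutpoints) + 1


@dataclass(frozen=True)
class WeightSet:
    """Stabilized weights for the two exposure occasions and their product."""

    w1: np.ndarray
    w2: np.ndarray
    w: np.ndarray
    truncation: tuple[float, float] | None = None
    model_provenance: dict = field(default_factory=dict)

    @classmethod
    def unit(cls, n: int) -> "WeightSet":
        ones = np.ones(n)
        return cls(w1=ones, w2=ones.copy(), w=ones.copy(),
                   model_provenance={"note": "unit weights"})


def assign_quantile_bins(x, k: int) -> QuantileBinning:
    """Assign each value to one of k equal-frequency bins.

    Boundaries are the empirical quantiles at j/k (linear interpolation);
    a value exactly on a boundary goes to the lower bin.  Missing values
    get a NaN label.
    """
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    obs = ~np.isnan(x)
    if obs.sum() < k:
        raise ValueError(
            f"need at least k = {k} non-missing values to form {k} bins, "
            f"got {int(obs.sum())}"
        )
    probs = np.arange(1, k) / k
    boundaries = np.quantile(x[obs], probs, method="linear")
    labels = np.full(x.shape, np.nan)
    # number of boundaries strictly below x, +1 → boundary values fall low
    labels[obs] = np.searchsorted(boundaries, x[obs], side="left") + 1.0
    counts = np.bincount(labels[obs].astype(int), minlength=k + 1)[1:]
    if np.any(counts == 0):
        empty = int(np.argmin(counts)) + 1
        raise ValueError(
            f"bin {empty} is empty after tie collapsing; lower k (ties in the "
            "exposure values prevent an equal-frequency split)"
        )
    return QuantileBinning(k=k, boundaries=boundaries, assignment=labels)


def _closed_form_cutpoints(bins: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    counts = np.bincount(bins.astype(int), minlength=k + 1)[1:]
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    cutpoints = np.log(cum / (1 - cum))
    loglik = float(np.sum(counts * np.log(counts / n)))
    return cutpoints, loglik


def fit_cumulative_logit(bins, covariates=None) -> OrdinalExposureModel:
    """Maximum-likelihood proportional-odds fit of bin labels on covariates.

    With no covariates the cutpoints are the logits of the cumulative bin
    frequencies (closed form).  The fit is invariant to covariate centering
    up to a shift of the cutpoints.
    """
    bins = np.asarray(bins, dtype=float)
    if np.any(np.isnan(bins)):
        raise ValueError("bin labels contain missing values")
    uniq = np.unique(bins)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct bins to fit an exposure model")
    k = int(bins.max())

    if covariates is None or (hasattr(covariates, "shape") and covariates.shape[1] == 0):
        cutpoints, loglik = _closed_form_cutpoints(bins, k)
        return OrdinalExposureModel(
            cutpoints=cutpoints,
            coefficients=np.empty(0),
            covariate_names=(),
            converged=True,
            loglik=loglik,
        )

    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        names = tuple(f"x{j}" for j in range(X.shape[1]))
    if np.any(np.isnan(X)):
        raise ValueError("covariates must be complete for included rows")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("covariate columns are collinear")

    endog = pd.Series(
        pd.Categorical(bins.astype(int), categories=list(range(1, k + 1)), ordered=True)
    )
    # fit on z-scored covariates for conditioning, then map back:
    # beta = beta_std / sd,  theta = theta_std + sum(beta_std * mu / sd)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    model = OrderedModel(endog, Xs, distr="logit")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gtol in (1e-9, 1e-7, 1e-5):
            res = model.fit(method="bfgs", maxiter=500, gtol=gtol, disp=False)
            if res.mle_retvals.get("converged", False):
                break
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(
            "cumulative-logit fit did not converge after 500 iterations: "
            f"{res.mle_retvals}"
        )
    beta_std = np.asarray(res.params[: X.shape[1]])
    cut_std = np.asarray(model.transform_threshold_params(res.params)[1:-1])
    beta = beta_std / sd
    cutpoints = cut_std + float(np.sum(beta_std * mu / sd))
    # scaled by covariate SDs so the check is scale-free
    if np.any(np.abs(beta * X.std(axis=0)) > 30):
        raise RuntimeError(
            "cumulative-logit coefficients diverged (complete separation); "
            "try fewer bins or fewer covariates"
        )
    return OrdinalExposureModel(
        cutpoints=np.asarray(cutpoints, dtype=float),
        coefficients=beta,
        covariate_names=names,
        converged=converged,
        loglik=float(res.llf),
    )


def bin_probabilities(model: OrdinalExposureModel, covariates=None) -> np.ndarray:
    """Per-subject probabilities over the K bins (rows sum to 1)."""
    if not model.converged:
        raise ValueError("exposure model did not converge")
    if len(model.covariate_names) == 0:
        if covariates is None:
            n = 1
        else:
            n = len(covariates)
        eta = np.zeros(n)
    else:
        if isinstance(covariates, pd.DataFrame):
            missing = [c for c in model.covariate_names if c not in covariates.columns]
            if missing:
                raise ValueError(f"covariate columns missing: {missing}")
            X = covariates.loc[:, list(model.covariate_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(covariates, dtype=float)
            if X.shape[1] != len(model.covariate_names):
                raise ValueError(
                    f"expected {len(model.covariate_names)} covariate columns, "
                    f"got {X.shape[1]}"
                )
        eta = X @ model.coefficients
    cum = 1.0 / (1.0 + np.exp(-(model.cutpoints[None, :] - eta[:, None])))
    cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
    return np.diff(cum, axis=1)


def stabilized_weights(p_marginal, p_conditional, observed_bin) -> np.ndarray:
    """w_i = P(bin = b_i) / P(bin = b_i | covariates_i).

    Raises on conditional probabilities below the positivity floor rather
    than silently producing near-infinite weights.
    """
    p_marginal = np.asarray(p_marginal, dtype=float)
    p_conditional = np.asarray(p_conditional, dtype=float)
    b = np.asarray(observed_bin, dtype=int) - 1
    idx = np.arange(len(b))
    denom = p_conditional[idx, b]
    bad = denom < PROBABILITY_FLOOR
    if np.any(bad):
        who = np.flatnonzero(bad)[:5].tolist()
        raise ValueError(
            f"positivity violation: conditional bin probability below "
            f"{PROBABILITY_FLOOR:g} for subjects {who}"
        )
    return p_marginal[b] / denom


def combine_weights(w1, w2, truncation: tuple[float, float] | None = None,
                    model_provenance: dict | None = None) -> WeightSet:
    """Elementwise product of the two occasions' weights, with optional
    winsorization at the given empirical percentiles of the product."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("w1 and w2 must have the same length")
    if np.any(w1 <= 0) or np.any(w2 <= 0):
        raise ValueError("weights must be strictly positive")
    w = w1 * w2
    if truncation is not None:
        # order-statistic percentiles: winsorize at observed weight values
        lo, hi = np.percentile(w, truncation, method="lower")
        w = np.clip(w, lo, hi)
    ws = WeightSet(
        w1=w1, w2=w2, w=w, truncation=truncation,
        model_provenance=model_provenance or {},
    )
    for name, col in (("w1", w1), ("w2", w2)):
        m = col.mean()
        if not (0.8 <= m <= 1.2):
            warnings.warn(
                f"mean of stabilized weight {name} is {m:.3f}, outside [0.8, 1.2]; "
                "the exposure model may be misspecified or positivity poor",
                stacklevel=2,
            )
    return ws


def exposure_weights(
    table: pd.DataFrame,
    exposure: str,
    covariates: Sequence[str],
    k: int = 8,
    stabilized: bool = True,
) -> tuple[np.ndarray, OrdinalExposureModel, QuantileBinning]:
    """One-occasion quantile-binned IPTW from a cohort table.

    Bins the exposure, fits the cumulative-logit model on the named
    covariates, and returns (weights, model, binning).  Rows must be
    complete in the exposure and covariates.
    """
    missing = [c for c in (exposure, *covariates) if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    binning = assign_quantile_bins(table[exposure].to_numpy(dtype=float), k)
    X = table.loc[:, list(covariates)] if covariates else None
    model = fit_cumulative_logit(binning.assignment, X)
    p_cond = bin_probabilities(model, X if covariates else table)
    if stabilized:
        counts = np.bincount(binning.assignment.astype(int), minlength=k + 1)[1:]
        p_marg = counts / counts.sum()
    else:
        p_marg = np.ones(k)
    w = stabilized_weights(p_marg, p_cond, binning.assignment)
    return w, model, binning


def iptw_weights(
    table: pd.DataFrame,
    z1: str,
    z2: str,
    z1_covariates: Sequence[str],
    z2_covariates: Sequence[str],
    k: int = 8,
    stabilized: bool = True,
    truncation: tuple[float, float] | None = None,
) -> WeightSet:
    """Combined weights for a two-occasion exposure sequence."""
    w1, m1, b1 = exposure_weights(table, z1, z1_covariates, k, stabilized)
    w2, m2, b2 = exposure_weights(table, z2, z2_covariates, k, stabilized)
    provenance = {
        "k": k,
        "stabilized": stabilized,
        "z1": {"exposure": z1, "covariates": list(z1_covariates),
               "cutpoints": m1.cutpoints.tolist(),
               "coefficients": m1.coefficients.tolist(), "loglik": m1.loglik},
        "z2": {"exposure": z2, "covariates": list(z2_covariates),
               "cutpoints": m2.cutpoints.tolist(),
               "coefficients": m2.coefficients.tolist(), "loglik": m2.loglik},
    }
    return combine_weights(w1, w2, truncation=truncation, model_provenance=provenance)
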