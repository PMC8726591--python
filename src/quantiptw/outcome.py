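"""Weighted outcome-model family for two-occasion continuous exposures.

Five models span the scientific hypotheses about exposure timing:

- ``differing``            y ~ z1 + z2          (combined weights)
- ``constant``             y ~ (z1 + z2)        (combined weights; equal
                                                 per-unit effects, only the
                                                 cumulative exposure matters)
- ``earlier_only_weighted_baseline``
                           y ~ z1               (occasion-1 weights only;
                                                 the "apparent" effect of
                                                 earlier exposure ignoring
                                                 later exposure)
- ``earlier_strong``       y ~ z1               (combined weights; later
                                                 exposure assumed inert)
- ``later_strong``         y ~ z2               (combined weights; earlier
                                                 exposure assumed inert)

Fits are weighted least squares (statsmodels WLS) with model-based SEs by
default (robust sandwich optional), AICc for small-sample model comparison,
a Wald test of equal effects, and calibration of fitted effects into
outcome-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .weighting import WeightSet

__all__ = [
    "OutcomeFit",
    "fit_wls",
    "fit_model_suite",
    "aicc",
    "test_equal_effects",
    "calibrate_effect",
    "standardized_difference",
    "classify_predictions",
]

MODEL_KINDS = (
    "differing",
    "constant",
    "earlier_only_weighted_baseline",
    "earlier_strong",
    "later_strong",
)


@dataclass(frozen=True)
class OutcomeFit:
    model_kind: str
    params: pd.Series  # alpha plus the relevant deltas
    ses: pd.Series
    cis: pd.DataFrame  # columns lo, hi
    tvalues: pd.Series
    pvalues: pd.Series
    std_coefs: pd.Series  # delta * SD_w(predictor) / SD_w(outcome)
    n: int
    k_params: int  # mean parameters + error variance
    df_resid: float
    loglik: float
    aic: float
    aicc: float
    cov_params: pd.DataFrame
    se_kind: str = "model-based WLS"
    weights_provenance: dict = field(default_factory=dict)

    @property
    def predictors(self) -> list[str]:
        return [p for p in self.params.index if p != "const"]


def _weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    m = np.sum(w * x) / sw
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / sw))


def fit_wls(
    y,
    design: pd.DataFrame,
    w=None,
    model_kind: str = "differing",
    robust: bool = False,
    weights_provenance: dict | None = None,
) -> OutcomeFit:
    """Weighted least squares of y on a design matrix (intercept added).

    Standard errors are model-based by default; ``robust=True`` switches to
    the HC0 sandwich, which IPTW theory prefers at the cost of small-sample
    noise.  The log-likelihood is the weighted Gaussian one (including the
    half-sum of log weights), so AICc comparisons across weight choices are
    coherent.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, dtype=float))
        design.columns = [f"x{j}" for j in range(design.shape[1])]
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if np.any(np.isnan(y)) or design.isna().any().any():
        raise ValueError("fit_wls requires complete rows")
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify the offending columns by incremental rank
        bad = []
        cols: list[str] = []
        for c in X.columns:
            trial = X[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(c)
            else:
                cols.append(c)
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    res = sm.WLS(y, X, weights=w).fit()
    if robust:
        res = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
        se_kind = "robust sandwich (HC0)"
    else:
        se_kind = "model-based WLS"

    n = len(y)
    p = X.shape[1]
    k = p + 1  # error variance counts as a parameter
    ll = float(res.llf)
    aic_val = -2 * ll + 2 * k
    # AICc is undefined right at n = k+1; report NaN rather than refuse the fit
    aicc_val = aicc(ll, k, n) if n > k + 1 else float("nan")
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["lo", "hi"]
    sd_y = _weighted_sd(y, w)
    std = {}
    for name in X.columns:
        if name == "const":
            std[name] = np.nan
        else:
            std[name] = res.params[name] * _weighted_sd(X[name].to_numpy(), w) / sd_y
    return OutcomeFit(
        model_kind=model_kind,
        params=res.params,
        ses=res.bse,
        cis=ci,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        std_coefs=pd.Series(std),
        n=n,
        k_params=k,
        df_resid=float(res.df_resid),
        loglik=ll,
        aic=aic_val,
        aicc=aicc_val,
        cov_params=res.cov_params(),
        se_kind=se_kind,
        weights_provenance=weights_provenance or {},
    )


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + (2k^2 + 2k) / (n - k - 1)."""
    if n <= k_params + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k_params + 1}")
    aic_val = -2 * loglik + 2 * k_params
    return aic_val + (2 * k_params**2 + 2 * k_params) / (n - k_params - 1)


def fit_model_suite(
    table: pd.DataFrame,
    z1: str,
    z2: str,
    y: str,
    weights: WeightSet,
    robust: bool = False,
) -> dict[str, OutcomeFit]:
    """Fit the five-hypothesis model family on one (completed) table."""
    yv = table[y].to_numpy(dtype=float)
    z1v = table[z1].to_numpy(dtype=float)
    z2v = table[z2].to_numpy(dtype=float)
    prov = dict(weights.model_provenance)
    cumulative = f"{z1}+{z2}"
    designs = {
        "differing": (pd.DataFrame({z1: z1v, z2: z2v}), weights.w),
        "constant": (pd.DataFrame({cumulative: z1v + z2v}), weights.w),
        "earlier_only_weighted_baseline": (pd.DataFrame({z1: z1v}), weights.w1),
        "earlier_strong": (pd.DataFrame({z1: z1v}), weights.w),
        "later_strong": (pd.DataFrame({z2: z2v}), weights.w),
    }
    return {
        kind: fit_wls(yv, X, w, model_kind=kind, robust=robust,
                      weights_provenance=prov)
        for kind, (X, w) in designs.items()
    }


def test_equal_effects(fit: OutcomeFit) -> dict[str, float | tuple[float, float]]:
    """Wald test of delta2 - delta1 = 0 on the differing-effects fit.

    Identical (to numerical precision) to refitting with the design
    reparameterized as (z1 + z2, z2 - z1) and reading the second
    coefficient.
    """
    if fit.model_kind != "differing" or len(fit.predictors) != 2:
        raise ValueError("equal-effects test needs a differing-effects fit")
    p1, p2 = fit.predictors
    est = float(fit.params[p2] - fit.params[p1])
    V = fit.cov_params
    var = float(V.loc[p2, p2] + V.loc[p1, p1] - 2 * V.loc[p1, p2])
    se = np.sqrt(var)
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    ci = (est - tcrit * se, est + tcrit * se)
    p = float(2 * stats.t.sf(abs(est) / se, fit.df_resid))
    return {"estimate": est, "se": float(se), "ci": ci, "p": p}


def _predict_profile(fit: OutcomeFit, profile: tuple[float, float]) -> float:
    z1p, z2p = float(profile[0]), float(profile[1])
    preds = fit.predictors
    a = float(fit.params.get("const", 0.0))
    if fit.model_kind == "constant":
        return a + float(fit.params[preds[0]]) * (z1p + z2p)
    if fit.model_kind == "differing":
        return a + float(fit.params[preds[0]]) * z1p + float(fit.params[preds[1]]) * z2p
    if fit.model_kind in ("earlier_only_weighted_baseline", "earlier_strong"):
        return a + float(fit.params[preds[0]]) * z1p
    if fit.model_kind == "later_strong":
        return a + float(fit.params[preds[0]]) * z2p
    raise ValueError(f"cannot predict for model kind {fit.model_kind!r}")


def calibrate_effect(
    fit: OutcomeFit,
    profile_low: tuple[float, float],
    profile_high: tuple[float, float],
    sd_outcome: float,
) -> dict[str, float]:
    """Predicted outcomes for two exposure profiles and their gap in
    outcome-SD units.  Profiles are (z1, z2) pairs; the intercept cancels
    in the difference."""
    if len(profile_low) != 2 or len(profile_high) != 2:
        raise ValueError("profiles must be (z1, z2) pairs")
    lo = _predict_profile(fit, profile_low)
    hi = _predict_profile(fit, profile_high)
    return {
        "predicted_low": lo,
        "predicted_high": hi,
        "difference": hi - lo,
        "standardized_difference": (hi - lo) / sd_outcome,
    }


def standardized_difference(predicted_low: float, predicted_high: float,
                            sd_outcome: float) -> float:
    """Gap between two predicted outcomes in outcome-SD units."""
    if sd_outcome <= 0:
        raise ValueError("sd_outcome must be positive")
    return (predicted_high - predicted_low) / sd_outcome


def classify_predictions(
    fit: OutcomeFit,
    table: pd.DataFrame,
    z1: str,
    z2: str,
    n_top: int = 16,
    n_bottom: int = 16,
) -> pd.DataFrame:
    """Label subjects by predicted-outcome rank: 'high' for the top
    ``n_top``, 'low' for the bottom ``n_bottom``, 'mid' otherwise.

    Ties are broken by stable subject (row) order.  Returns a plot-ready
    frame of (z1, z2, predicted, label); plotting the points against the
    z2 = z1 equality line shows which exposure *sequences* the model
    rewards.
    """
    n = len(table)
    if n_top + n_bottom > n:
        raise ValueError(f"n_top + n_bottom = {n_top + n_bottom} exceeds n = {n}")
    z1v = table[z1].to_numpy(dtype=float)
    z2v = table[z2].to_numpy(dtype=float)
    pred = np.array([_predict_profile(fit, (a, b)) for a, b in zip(z1v, z2v)])
    order = np.argsort(pred, kind="stable")
    labels = np.array(["mid"] * n, dtype=object)
    labels[order[:n_bottom]] = "low"
    labels[order[n - n_top:]] = "high"
    return pd.DataFrame({z1: z1v, z2: z2v, "predicted": pred, "label": labels})
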