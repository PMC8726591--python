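"""Multiple imputation by chained equations with predictive mean matching,
and Rubin's-rules pooling of downstream estimates.

Predictive mean matching (PMM) imputes a missing cell with an *observed*
value borrowed from a donor whose model-predicted mean is close to the
missing case's prediction, so imputations respect the support and shape of
the observed data.  Each chained-equations sweep regresses one incomplete
column on all the others (current completed values), draws regression
parameters from their approximate posterior, and samples one of the
``donor_k`` nearest donors per missing cell.

Pooling follows Rubin's rules with the Barnard-Rubin small-sample degrees
of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationSet", "PooledFit", "pmm_impute", "rubin_pool"]


@dataclass(frozen=True)
class ImputationSet:
    tables: tuple[pd.DataFrame, ...]
    m: int
    donor_k: int
    sweeps: int
    seed: int

    def __iter__(self):
        return iter(self.tables)

    def __len__(self):
        return self.m


@dataclass(frozen=True)
class PooledFit:
    estimate: float  # Q-bar
    within: float  # W, mean of squared SEs
    between: float  # B, sample variance of estimates
    total: float  # T = W + (1 + 1/m) B
    se: float
    df: float
    ci: tuple[float, float]
    p: float
    m: int


def _pmm_column(
    y: np.ndarray,
    X: np.ndarray,
    miss: np.ndarray,
    donor_k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One PMM draw for one column. X is complete; y[miss] are the targets."""
    obs = ~miss
    Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
    Xm = np.column_stack([np.ones(miss.sum()), X[miss]])
    yo = y[obs]
    n, p = Xo.shape
    # ridge epsilon guards against collinear predictors mid-chain
    xtx = Xo.T @ Xo + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(xtx, Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    # Bayesian draw: sigma^2 from scaled inv-chi^2, beta ~ N(beta_hat, sigma^2 (X'X)^-1)
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(xtx)
    beta_star = rng.multivariate_normal(beta_hat, cov)  # svd: tolerates PSD
    # type-1 matching: donors predicted with beta_hat, targets with beta_star
    pred_obs = Xo @ beta_hat
    pred_mis = Xm @ beta_star
    out = y.copy()
    kk = min(donor_k, len(yo))
    dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
    part = np.argpartition(dist, kk - 1, axis=1)[:, :kk]
    choice = rng.integers(0, kk, size=len(pred_mis))
    out[miss] = yo[part[np.arange(len(pred_mis)), choice]]
    return out


def pmm_impute(
    table: pd.DataFrame,
    m: int = 5,
    donor_k: int = 5,
    sweeps: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equations PMM producing ``m`` completed tables.

    Non-numeric columns must be complete (they are carried through).  A
    table with no missing cells yields ``m`` identical copies.
    """
    numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    miss_cols = [c for c in numeric if table[c].isna().any()]
    for c in table.columns:
        if c not in numeric and table[c].isna().any():
            raise ValueError(f"non-numeric column {c!r} has missing values")
    for c in miss_cols:
        n_obs = table[c].notna().sum()
        if n_obs == 0:
            raise ValueError(f"column {c!r} is entirely missing; cannot impute")
        if n_obs < donor_k:
            raise ValueError(
                f"column {c!r} has only {n_obs} observed values, fewer than "
                f"donor_k={donor_k}"
            )
    if not any(table[c].notna().all() for c in numeric):
        raise ValueError("need at least one fully observed numeric column")

    completed = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(m):
        rng = np.random.default_rng(child)
        data = {c: table[c].to_numpy(dtype=float).copy() for c in numeric}
        masks = {c: np.isnan(data[c]) for c in miss_cols}
        # initialize by random draws from the observed values
        for c in miss_cols:
            obs_vals = data[c][~masks[c]]
            data[c][masks[c]] = rng.choice(obs_vals, size=masks[c].sum())
        predictors = {c: [o for o in numeric if o != c] for c in miss_cols}
        for _ in range(max(sweeps, 1) if miss_cols else 0):
            for c in miss_cols:
                X = np.column_stack([data[o] for o in predictors[c]])
                y = _with_current(table[c].to_numpy(dtype=float), data[c], masks[c])
                data[c] = _pmm_column(y, X, masks[c], donor_k, rng)
        out = table.copy()
        for c in numeric:
            out[c] = data[c]
        completed.append(out)
    return ImputationSet(
        tables=tuple(completed), m=m, donor_k=donor_k, sweeps=sweeps, seed=seed
    )


def _with_current(original: np.ndarray, current: np.ndarray, miss: np.ndarray) -> np.ndarray:
    """Observed cells from the original column, current fills elsewhere."""
    out = current.copy()
    out[~miss] = original[~miss]
    return out


def rubin_pool(estimates, ses, df_complete: float | None = None) -> PooledFit:
    """Pool per-imputation estimates and standard errors.

    Q-bar = mean estimate; W = mean(se^2); B = sample variance of the
    estimates; T = W + (1 + 1/m) B.  Degrees of freedom follow the
    Barnard-Rubin small-sample formula when ``df_complete`` (the
    complete-data residual df) is given, else the classic large-sample
    Rubin df.
    """
    q = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError(f"need m >= 2 imputations to pool, got {m}")
    if np.any(s <= 0):
        raise ValueError("standard errors must be strictly positive")
    qbar = float(q.mean())
    W = float(np.mean(s**2))
    B = float(np.var(q, ddof=1))
    T = W + (1 + 1 / m) * B
    if B == 0:
        df = np.inf if df_complete is None else float(df_complete)
    else:
        r = (1 + 1 / m) * B / W
        df_old = (m - 1) * (1 + 1 / r) ** 2
        if df_complete is None:
            df = df_old
        else:
            lam = (1 + 1 / m) * B / T
            df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = float(np.sqrt(T))
    tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
    ci = (qbar - tcrit * se, qbar + tcrit * se)
    if np.isfinite(df):
        p = float(2 * stats.t.sf(abs(qbar) / se, df))
    else:
        p = float(2 * stats.norm.sf(abs(qbar) / se))
    return PooledFit(
        estimate=qbar, within=W, between=B, total=T, se=se, df=float(df),
        ci=ci, p=p, m=m,
    )
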