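"""Weighted balance diagnostics and balance-driven covariate selection.

A propensity model has done its job when, in the weighted sample, the
exposure is unassociated with every candidate confounder.  Because the
exposure here is continuous, the primary balance metric is the absolute
weighted Pearson correlation between exposure and covariate (threshold 0.1
by default); effective sample size and weight extrema summarize common
support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .weighting import exposure_weights

__all__ = [
    "BalanceReport",
    "weighted_correlation",
    "effective_sample_size",
    "balance_report",
    "select_covariates",
]


@dataclass(frozen=True)
class BalanceReport:
    table: pd.DataFrame  # per covariate: unweighted, weighted, passed
    threshold: float
    ess: float
    max_weight: float
    min_weight: float
    metric: str = "absolute weighted Pearson correlation (magnitude criterion)"

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())

    @property
    def worst(self) -> str:
        idx = self.table["weighted"].abs().idxmax()
        return str(self.table.loc[idx, "covariate"])


def weighted_correlation(x, y, w) -> float:
    """Pearson correlation under weight-normalized moments.

    Reduces to the ordinary correlation when the weights are equal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(w))
    x, y, w = x[ok], y[ok], w[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 complete (x, y, w) triples")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    vx = np.sum(w * (x - mx) ** 2) / sw
    vy = np.sum(w * (y - my) ** 2) / sw
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance; correlation undefined")
    cov = np.sum(w * (x - mx) * (y - my)) / sw
    return float(cov / np.sqrt(vx * vy))


def effective_sample_size(w) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2, in [1, n]."""
    w = np.asarray(w, dtype=float)
    if len(w) == 0:
        raise ValueError("empty weight vector")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    return float(w.sum() ** 2 / np.sum(w**2))


def balance_report(
    table: pd.DataFrame,
    weights,
    exposure: str,
    covariates: Sequence[str],
    threshold: float = 0.1,
) -> BalanceReport:
    """Weighted vs unweighted exposure-covariate associations.

    ``weights`` may be a plain vector or a ``WeightSet`` (its combined
    column ``w`` is used).  Covariates need not appear in the exposure
    model — checking balance on *all* candidates is the point.
    """
    w = np.asarray(getattr(weights, "w", weights), dtype=float)
    if len(w) != len(table):
        raise ValueError("weights are not aligned to the table rows")
    unknown = [c for c in (exposure, *covariates) if c not in table.columns]
    if unknown:
        raise ValueError(f"unknown columns: {unknown}")
    x = table[exposure].to_numpy(dtype=float)
    rows = []
    for cov in covariates:
        y = table[cov].to_numpy(dtype=float)
        raw = weighted_correlation(x, y, np.ones_like(w))
        wtd = weighted_correlation(x, y, w)
        rows.append(
            {"covariate": cov, "unweighted": raw, "weighted": wtd,
             "passed": abs(wtd) < threshold}
        )
    return BalanceReport(
        table=pd.DataFrame(rows),
        threshold=threshold,
        ess=effective_sample_size(w),
        max_weight=float(w.max()),
        min_weight=float(w.min()),
    )


def select_covariates(
    table: pd.DataFrame,
    exposure: str,
    candidate_covariates: Sequence[str],
    k: int = 8,
    threshold: float = 0.1,
    max_steps: int | None = None,
    extra_weights=None,
) -> tuple[list[str], list[BalanceReport], BalanceReport]:
    """Greedy forward covariate selection until all candidates balance.

    Start from the empty exposure model; at each step compute the weighted
    balance of every candidate and, if any exceeds the threshold, add the
    worst offender to the model and refit.  Stops when all pass, candidates
    are exhausted, or ``max_steps`` is reached (the final report's
    ``all_passed`` flag then records failure — no exception).

    ``extra_weights`` (optional, per-subject) are multiplied into the
    weights before the balance check; pass the first-occasion weights here
    when selecting the second-occasion model so balance is judged under the
    combined weight.
    """
    if max_steps is None:
        max_steps = len(candidate_covariates)
    selected: list[str] = []
    trace: list[BalanceReport] = []
    extra = None if extra_weights is None else np.asarray(extra_weights, dtype=float)

    def current_report() -> BalanceReport:
        w, _, _ = exposure_weights(table, exposure, selected, k=k)
        if extra is not None:
            w = w * extra
        return balance_report(table, w, exposure, candidate_covariates, threshold)

    report = current_report()
    trace.append(report)
    steps = 0
    while not report.all_passed and steps < max_steps:
        remaining = [c for c in candidate_covariates if c not in selected]
        if not remaining:
            break
        failing = report.table[~report.table["passed"]]
        failing = failing[failing["covariate"].isin(remaining)]
        if failing.empty:
            break  # every failing candidate is already in the model
        worst = failing.loc[failing["weighted"].abs().idxmax(), "covariate"]
        selected.append(str(worst))
        report = current_report()
        trace.append(report)
        steps += 1
    return selected, trace, report
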