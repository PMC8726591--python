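"""Synthetic longitudinal cohorts with known causal structure.

The generator emulates a small observational cohort in which a continuous
"exposure" is measured twice (earlier input ``z1``, later input ``z2``),
a time-varying covariate ``x1`` sits between the two exposure occasions,
and a continuous outcome ``y`` is measured at the end.  Baseline covariates
(household income, caregiver education and verbal IQ, child gender, birth
order, and early child word/gesture counts) confound the exposures, and
``x1`` is both a consequence of ``z1`` and a cause of ``z2`` and ``y`` —
the classic time-varying-confounding structure that motivates marginal
structural models.

All structural equations are linear with Gaussian noise::

    z1 = mu_z1 + gamma0' x0s + a_u * sigma_z1 * U + N(0, sigma_z1)
    x1 = lambda_z1_x1 * (z1 - mu_z1) + lambda_x0_x1' x0s + N(0, sigma_x1)
    z2 = mu_z2 + kappa_z1_z2 * (z1 - mu_z1) + kappa_x1_z2 * x1
         + kappa_x0_z2' x0s + a_u * sigma_z2 * U + N(0, sigma_z2)
    y  = alpha + delta1 * z1 + delta2 * z2 + eta_x1_y * x1
         + eta_x0_y' x0s + b_u * sigma_y * U + N(0, sigma_y)

where ``x0s`` are the baseline covariates standardized by fixed nominal
moments (so the truth parameters do not depend on the realized sample) and
``U`` is an optional unmeasured standard-normal confounder used by the
sensitivity analysis.

Because ``x1`` mediates part of the effect of ``z1`` on ``y``, the joint
intervention ("set z1 and z2") effect of ``z1`` is
``delta1 + eta_x1_y * lambda_z1_x1``, exposed as :attr:`TruthParams.msm_delta1`;
this is the estimand a correctly weighted marginal structural model targets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TruthParams",
    "BASELINE_COLUMNS",
    "COHORT_COLUMNS",
    "generate_cohort",
    "apply_missingness",
    "composite_child_language",
    "clauses_per_100_sentences",
    "write_cohort",
    "read_cohort",
    "truth_vocab",
    "truth_syntax",
    "truth_strong_confounding",
    "truth_moderate_confounding",
    "truth_null_confounding",
]

BASELINE_COLUMNS = (
    "income",
    "education",
    "parent_verbal_iq",
    "child_gender",
    "birth_order",
    "child_word_types_14",
    "child_gesture_types_14",
)

COHORT_COLUMNS = BASELINE_COLUMNS + ("z1", "x1", "z2", "y")

# Fixed nominal moments used to standardize baseline covariates inside the
# structural equations.  Chosen to match the cohort the generator emulates;
# fixed constants keep the truth parameters independent of the realized draw.
_NOMINAL_MOMENTS: dict[str, tuple[float, float]] = {
    "income": (60.2, 31.4),
    "education": (15.7, 2.2),
    "parent_verbal_iq": (57.9, 10.7),
    "child_gender": (0.5, 0.5),
    "birth_order": (0.5, 0.5),
    "child_word_types_14": (14.1, 14.6),
    "child_gesture_types_14": (21.7, 12.5),
}

_INCOME_MIDPOINTS = np.array([7.5, 25.0, 42.5, 62.5, 87.5, 100.0])
_INCOME_PROBS = np.array([0.14, 0.14, 0.12, 0.18, 0.12, 0.30])
_EDUCATION_LEVELS = np.array([10.0, 12.0, 14.0, 16.0, 18.0])
_EDUCATION_PROBS = np.array([0.05, 0.15, 0.20, 0.35, 0.25])


@dataclass(frozen=True)
class TruthParams:
    """Generator truth for one synthetic cohort.

    Path coefficients are in raw units of the variables they connect, except
    for baseline-covariate effects (``gamma0``, ``lambda_x0_x1``,
    ``kappa_x0_z2``, ``eta_x0_y``) which apply to covariates standardized by
    fixed nominal moments, i.e. they are "per covariate SD".
    """

    n: int = 64
    seed: int = 0
    alpha: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    gamma0: Mapping[str, float] = field(default_factory=dict)
    lambda_z1_x1: float = 0.0
    lambda_x0_x1: Mapping[str, float] = field(default_factory=dict)
    kappa_z1_z2: float = 0.0
    kappa_x1_z2: float = 0.0
    kappa_x0_z2: Mapping[str, float] = field(default_factory=dict)
    eta_x0_y: Mapping[str, float] = field(default_factory=dict)
    eta_x1_y: float = 0.0
    sigma_z1: float = 1.0
    sigma_x1: float = 1.0
    sigma_z2: float = 1.0
    sigma_y: float = 1.0
    miss_rates: Mapping[str, float] = field(default_factory=dict)
    mu_z1: float = 404.0
    mu_z2: float = 464.0
    exposure_kind: str = "vocab"
    # unmeasured-confounder strengths, in noise-SD units (sensitivity analysis)
    u_exposure: float = 0.0
    u_outcome: float = 0.0

    @property
    def msm_delta1(self) -> float:
        """Joint-intervention effect of z1 (direct + via x1)."""
        return self.delta1 + self.eta_x1_y * self.lambda_z1_x1

    @property
    def msm_delta2(self) -> float:
        """Joint-intervention effect of z2."""
        return self.delta2

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError(f"n must be >= 10, got {self.n}")
        for name in ("sigma_z1", "sigma_x1", "sigma_z2", "sigma_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for col, rate in self.miss_rates.items():
            if not (0 <= rate < 1):
                raise ValueError(f"miss_rates[{col!r}] must be in [0, 1), got {rate}")
        if self.exposure_kind not in ("vocab", "syntax"):
            raise ValueError(f"exposure_kind must be 'vocab' or 'syntax', got {self.exposure_kind!r}")
        for mapping_name in ("gamma0", "lambda_x0_x1", "kappa_x0_z2", "eta_x0_y"):
            for col in getattr(self, mapping_name):
                if col not in BASELINE_COLUMNS:
                    raise ValueError(f"{mapping_name} names unknown covariate {col!r}")

    def replace(self, **changes) -> "TruthParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("gamma0", "lambda_x0_x1", "kappa_x0_z2", "eta_x0_y", "miss_rates"):
            d[key] = dict(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthParams":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def _standardize_baseline(table: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col in BASELINE_COLUMNS:
        mu, sd = _NOMINAL_MOMENTS[col]
        out[col] = (table[col] - mu) / sd
    return pd.DataFrame(out)


def _draw_baseline(n: int, rng: np.random.Generator) -> pd.DataFrame:
    income = rng.choice(_INCOME_MIDPOINTS, size=n, p=_INCOME_PROBS)
    education = rng.choice(_EDUCATION_LEVELS, size=n, p=_EDUCATION_PROBS)
    # verbal IQ t score, truncated to the plausible instrument range
    a, b = (20 - 57.9) / 10.7, (80 - 57.9) / 10.7
    iq = stats.truncnorm.rvs(a, b, loc=57.9, scale=10.7, size=n, random_state=rng)
    gender = rng.integers(0, 2, size=n).astype(float)
    birth = rng.integers(0, 2, size=n).astype(float)
    # right-skewed early word/gesture counts (median well below mean)
    word = np.round(rng.lognormal(mean=np.log(8.5), sigma=1.0, size=n))
    gesture = np.round(rng.lognormal(mean=np.log(18.5), sigma=0.55, size=n))
    return pd.DataFrame(
        {
            "income": income,
            "education": education,
            "parent_verbal_iq": iq,
            "child_gender": gender,
            "birth_order": birth,
            "child_word_types_14": word,
            "child_gesture_types_14": gesture,
        }
    )


def _linear_combo(x0s: pd.DataFrame, coefs: Mapping[str, float]) -> np.ndarray:
    total = np.zeros(len(x0s))
    for col, c in coefs.items():
        total += c * x0s[col].to_numpy()
    return total


def generate_cohort(params: TruthParams) -> tuple[pd.DataFrame, TruthParams]:
    """Draw one cohort from the structural equations.

    Returns the cohort table and an echo of the params used.  The same
    params (including seed) always produce a bitwise-identical table.
    Missingness is applied afterwards per ``params.miss_rates`` using the
    MAR-on-observed mechanism; pass empty ``miss_rates`` for complete data.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n

    table = _draw_baseline(n, rng)
    x0s = _standardize_baseline(table)

    u = rng.standard_normal(n)

    z1 = (
        params.mu_z1
        + _linear_combo(x0s, params.gamma0)
        + params.u_exposure * params.sigma_z1 * u
        + rng.normal(0.0, params.sigma_z1, n)
    )
    if params.exposure_kind == "syntax":
        z1 = np.maximum(z1, 100.0)  # every complete sentence has >= 1 clause

    x1 = (
        params.lambda_z1_x1 * (z1 - params.mu_z1)
        + _linear_combo(x0s, params.lambda_x0_x1)
        + rng.normal(0.0, params.sigma_x1, n)
    )

    z2 = (
        params.mu_z2
        + params.kappa_z1_z2 * (z1 - params.mu_z1)
        + params.kappa_x1_z2 * x1
        + _linear_combo(x0s, params.kappa_x0_z2)
        + params.u_exposure * params.sigma_z2 * u
        + rng.normal(0.0, params.sigma_z2, n)
    )
    if params.exposure_kind == "syntax":
        z2 = np.maximum(z2, 100.0)

    y = (
        params.alpha
        + params.delta1 * z1
        + params.delta2 * z2
        + params.eta_x1_y * x1
        + _linear_combo(x0s, params.eta_x0_y)
        + params.u_outcome * params.sigma_y * u
        + rng.normal(0.0, params.sigma_y, n)
    )

    table["z1"] = z1
    table["x1"] = x1
    table["z2"] = z2
    table["y"] = y
    if params.u_exposure != 0.0 or params.u_outcome != 0.0:
        table["u"] = u  # the unmeasured confounder; analyses must omit it

    if params.miss_rates:
        table = apply_missingness(
            table, params.miss_rates, mechanism="MAR-on-observed", seed=params.seed + 1
        )
    return table, params


def apply_missingness(
    table: pd.DataFrame,
    miss_rates: Mapping[str, float],
    mechanism: str = "MCAR",
    seed: int = 0,
) -> pd.DataFrame:
    """Blank out cells at the requested per-column rates.

    ``MCAR`` blanks each cell independently.  ``MAR-on-observed`` makes the
    missingness probability a logistic function of standardized household
    income and education (which therefore must stay fully observed), with
    the intercept calibrated so the marginal rate matches the request.
    The input table is never modified.
    """
    if mechanism not in ("MCAR", "MAR-on-observed"):
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    for col, rate in miss_rates.items():
        if col not in table.columns:
            raise ValueError(f"miss_rates names unknown column {col!r}")
        if not (0 <= rate < 1):
            raise ValueError(
                f"miss_rates[{col!r}] must be in [0, 1), got {rate} "
                "(a rate of 1.0 would delete the column)"
            )

    out = table.copy()
    rng = np.random.default_rng(seed)
    n = len(table)

    if mechanism == "MAR-on-observed":
        drivers = ("income", "education")
        for col in miss_rates:
            if col in drivers and miss_rates[col] > 0:
                raise ValueError(
                    f"MAR-on-observed drives missingness from {drivers}; "
                    f"column {col!r} must stay fully observed"
                )
        mu_i, sd_i = _NOMINAL_MOMENTS["income"]
        mu_e, sd_e = _NOMINAL_MOMENTS["education"]
        score = -0.7 * (
            (table["income"].to_numpy() - mu_i) / sd_i
            + (table["education"].to_numpy() - mu_e) / sd_e
        ) / np.sqrt(2.0)

    for col, rate in miss_rates.items():
        if rate == 0:
            continue
        if mechanism == "MCAR":
            mask = rng.random(n) < rate
        else:
            # calibrate the intercept so the mean probability equals `rate`
            c = optimize.brentq(
                lambda c_: np.mean(_sigmoid(c_ + score)) - rate, -30.0, 30.0
            )
            mask = rng.random(n) < _sigmoid(c + score)
        out.loc[mask, col] = np.nan
    return out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    obs = ~np.isnan(v)
    if obs.sum() < 2:
        raise ValueError(f"column {name!r} needs >= 2 non-missing values")
    sd = np.std(v[obs], ddof=1)
    if sd == 0:
        raise ValueError(f"column {name!r} has zero variance; cannot z-score")
    out = np.full_like(v, np.nan, dtype=float)
    out[obs] = (v[obs] - np.mean(v[obs])) / sd
    return out


def composite_child_language(word_types_26, mlu_26) -> np.ndarray:
    """Average of the z-scores of child word types and MLU at 26 months.

    Each input is z-scored over its non-missing entries (sample SD, n-1
    denominator); the composite is the elementwise mean and is missing
    wherever either input is missing.
    """
    w = np.asarray(word_types_26, dtype=float)
    m = np.asarray(mlu_26, dtype=float)
    if w.shape != m.shape:
        raise ValueError("word_types_26 and mlu_26 must have the same length")
    zw = _zscore(w, "word_types_26")
    zm = _zscore(m, "mlu_26")
    return (zw + zm) / 2.0


def clauses_per_100_sentences(total_clauses, total_complete_sentences) -> float:
    """Syntactic-complexity rate: 100 * clauses / complete sentences.

    Bounded below by 100 because every complete sentence contains at least
    one clause.
    """
    c = np.asarray(total_clauses, dtype=float)
    s = np.asarray(total_complete_sentences, dtype=float)
    if np.any(s < 1):
        raise ValueError("total_complete_sentences must be >= 1")
    if np.any(c < s):
        raise ValueError(
            "total_clauses must be >= total_complete_sentences "
            "(each complete sentence contains at least one clause)"
        )
    out = 100.0 * c / s
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(table: pd.DataFrame, path, params: TruthParams | None = None) -> None:
    """Write a cohort as CSV (missing cells as empty fields); params as JSON."""
    path = Path(path)
    table.to_csv(path, index=False, na_rep="")
    if params is not None:
        params_path = path.with_suffix(".params.json")
        params_path.write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_cohort(path) -> tuple[pd.DataFrame, TruthParams | None]:
    path = Path(path)
    table = pd.read_csv(path, float_precision="round_trip")
    params_path = path.with_suffix(".params.json")
    params = None
    if params_path.exists():
        params = TruthParams.from_dict(json.loads(params_path.read_text()))
    return table, params


# ---------------------------------------------------------------------------
# presets — each states one synthetic world and is not meant to be re-tuned


def truth_vocab(n: int = 64, seed: int = 0) -> TruthParams:
    """Vocabulary-input world: word-types scales, equal joint effects.

    The direct effect of z1 (0.0105) plus its path through the time-varying
    covariate (3.0 * 0.0035) equals the z2 effect, so the constant-effects
    model is the true description on the intervention scale.
    """
    return TruthParams(
        n=n,
        seed=seed,
        alpha=92.0,
        delta1=0.0105,
        delta2=0.021,
        gamma0={"parent_verbal_iq": 40.0, "income": 30.0, "child_gender": 10.0},
        lambda_z1_x1=0.0035,
        lambda_x0_x1={"parent_verbal_iq": 0.25, "income": 0.15},
        kappa_z1_z2=0.45,
        kappa_x1_z2=35.0,
        kappa_x0_z2={"income": 15.0},
        eta_x0_y={"parent_verbal_iq": 4.0, "income": 3.0, "education": 2.0},
        eta_x1_y=3.0,
        sigma_z1=110.0,
        sigma_x1=0.65,
        sigma_z2=85.0,
        sigma_y=10.0,
        miss_rates={"parent_verbal_iq": 13 / 64, "x1": 3 / 64, "z2": 3 / 64, "y": 4 / 64},
        mu_z1=404.0,
        mu_z2=464.0,
        exposure_kind="vocab",
    )


def truth_syntax(n: int = 64, seed: int = 0) -> TruthParams:
    """Syntax-input world: clauses-per-100-sentences scales, differing effects
    (earlier complexity harmful, later complexity helpful, on the
    intervention scale: msm_delta1 = -0.24, msm_delta2 = 0.22)."""
    return TruthParams(
        n=n,
        seed=seed,
        alpha=18.4,
        delta1=-0.304,
        delta2=0.22,
        gamma0={"parent_verbal_iq": 1.4, "birth_order": 0.8, "child_word_types_14": 1.0},
        lambda_z1_x1=0.08,
        lambda_x0_x1={"parent_verbal_iq": 0.25, "child_word_types_14": 0.3},
        kappa_z1_z2=0.45,
        kappa_x1_z2=2.0,
        kappa_x0_z2={"parent_verbal_iq": 1.0, "education": 0.8, "child_gender": 0.5},
        eta_x0_y={"parent_verbal_iq": 0.8, "education": 0.5},
        eta_x1_y=0.8,
        sigma_z1=3.5,
        sigma_x1=0.65,
        sigma_z2=4.8,
        sigma_y=2.2,
        miss_rates={"parent_verbal_iq": 13 / 64, "x1": 3 / 64, "z2": 3 / 64, "y": 10 / 64},
        mu_z1=110.0,
        mu_z2=117.0,
        exposure_kind="syntax",
    )


def truth_strong_confounding(n: int = 2000, seed: int = 0) -> TruthParams:
    """Word-types world with strong baseline and time-varying confounding.

    Unweighted exposure-confounder correlations exceed 0.3 and the naive
    regression of y on (z1, z2) is badly biased (asymptotically ~ +38% on
    the later-exposure coefficient); used by the simulation studies to show
    what weighting buys.  Quantile binning removes only between-bin
    confounding, so the path strengths sit where the naive analysis is
    clearly wrong while the within-bin residual stays small relative to
    the effects.
    """
    return TruthParams(
        n=n,
        seed=seed,
        alpha=92.0,
        delta1=0.029 - 0.9 * 0.0025,  # msm_delta1 = 0.029 after the x1 path
        delta2=0.029,
        gamma0={"parent_verbal_iq": 45.0, "income": 34.0},
        lambda_z1_x1=0.0025,
        lambda_x0_x1={"parent_verbal_iq": 0.2, "income": 0.15},
        kappa_z1_z2=0.35,
        kappa_x1_z2=9.0,
        kappa_x0_z2={"income": 18.0, "parent_verbal_iq": 13.5},
        eta_x0_y={"parent_verbal_iq": 3.0, "income": 2.2},
        eta_x1_y=0.9,
        sigma_z1=100.0,
        sigma_x1=0.65,
        sigma_z2=85.0,
        sigma_y=9.5,
        miss_rates={},
        exposure_kind="vocab",
    )


def truth_moderate_confounding(n: int = 1000, seed: int = 0) -> TruthParams:
    """Well-specified world with moderate confounding; used for CI-coverage
    checks of the weighted estimator."""
    return TruthParams(
        n=n,
        seed=seed,
        alpha=92.0,
        delta1=0.021,
        delta2=0.029,
        gamma0={"parent_verbal_iq": 30.0, "income": 22.0},
        lambda_z1_x1=0.004,
        lambda_x0_x1={"parent_verbal_iq": 0.15, "income": 0.1},
        kappa_z1_z2=0.4,
        kappa_x1_z2=25.0,
        kappa_x0_z2={"income": 10.0},
        eta_x0_y={"parent_verbal_iq": 3.0, "income": 2.0},
        eta_x1_y=2.0,
        sigma_z1=115.0,
        sigma_x1=0.8,
        sigma_z2=100.0,
        sigma_y=10.0,
        miss_rates={},
        exposure_kind="vocab",
    )


def truth_null_confounding(n: int = 2000, seed: int = 0) -> TruthParams:
    """Exposures independent of all covariates; weights should be ~1."""
    return TruthParams(
        n=n,
        seed=seed,
        alpha=92.0,
        delta1=0.021,
        delta2=0.021,
        gamma0={},
        lambda_z1_x1=0.0,
        lambda_x0_x1={},
        kappa_z1_z2=0.5,
        kappa_x1_z2=0.0,
        kappa_x0_z2={},
        eta_x0_y={},
        eta_x1_y=0.0,
        sigma_z1=110.0,
        sigma_x1=0.9,
        sigma_z2=95.0,
        sigma_y=10.0,
        miss_rates={},
        exposure_kind="vocab",
    )
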