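# Methods

## Causal structure and estimand

The package targets a two-occasion continuous-exposure design: baseline
covariates X0, an earlier exposure Z1, a time-varying covariate X1 measured
between occasions, a later exposure Z2, and a continuous outcome Y. The
assumed causal graph is X0 → {Z1, X1, Z2, Y}, Z1 → {X1, Z2, Y},
X1 → {Z2, Y}, Z2 → Y. X1 is simultaneously a mediator of Z1 and a
confounder of Z2 — the configuration in which neither adjusting nor not
adjusting for X1 in an outcome regression is valid, and which motivates
inverse-probability weighting of a marginal structural model (MSM).

The estimand is the joint-intervention ("set Z1 and Z2") effect pair. In
the synthetic worlds, where Y depends on Z1 directly (δ₁) and X1 carries a
further Z1 path (Z1 → X1 → Y with coefficients λ and η), the MSM truth is

```
δ₁* = δ₁ + η·λ        δ₂* = δ₂
```

exposed as `TruthParams.msm_delta1/msm_delta2`; all simulation metrics are
computed against these, not against the raw structural δ₁.

## Weighting

- **Binning.** Empirical quantiles at probabilities j/K (linear
  interpolation), values equal to a boundary going to the lower bin;
  K = 8 by default. Binning is deterministic in the multiset of values, and
  an empty bin after tie collapsing is an error instructing the user to
  lower K.
- **Exposure model.** Proportional-odds cumulative logit,
  P(bin ≤ j | x) = logistic(θⱼ − x'β), fitted by maximum likelihood
  (statsmodels `OrderedModel`). Covariates are z-scored internally for
  conditioning and the coefficients mapped back, with a tiered
  gradient-tolerance schedule (1e-9 → 1e-7 → 1e-5) so well-posed problems
  get near-machine precision while hard ones still converge; intercept-only
  models use the closed form θⱼ = logit(cumulative frequency). Coefficients
  whose standardized magnitude exceeds 30 are treated as complete
  separation and rejected.
- **Weights.** Stabilized by default: numerator = marginal bin
  frequencies, denominator = model probability of the observed bin, with a
  positivity floor of 1e-6 (an informative error, never a silent huge
  weight). Occasion weights multiply; optional winsorization uses
  order-statistic percentiles. A soft check warns when a stabilized-weight
  mean leaves [0.8, 1.2].

**Known, quantified limitation: within-bin residual confounding.** The
weights balance *bin membership* only; the outcome model uses the
continuous exposure, so confounding carried by within-bin exposure
variation survives. Measured on bivariate-normal exposure/confounder data
at K = 8, the surviving bias is roughly 10% of the naive bias with
analytically true weights and ~15–20% with estimated logit weights
(link misspecification: the synthetic exposures are probit-consistent).
Consequently the method is accurate when raw exposure-confounder
correlations are moderate (≲ 0.4), and the bin-count sweep shows bias
shrinking as K grows. The strong-confounding preset was placed, by
asymptotic probes run before any test was frozen, in the window where the
naive analysis is clearly wrong (later-exposure bias ≈ +38%) while the
weighted residual stays well under 10% of the effect.

## Balance and covariate selection

Balance metric: absolute weighted Pearson correlation between the
continuous exposure and each candidate covariate (weight-normalized
moments), threshold 0.1; the report also carries the Kish effective sample
size (Σw)²/Σw² and weight extrema. Selection is greedy-forward: start from
an empty exposure model, add the worst-offending unbalanced candidate,
refit, stop when all candidates pass (or return a not-balanced flag —
never an exception). For the second occasion, balance is judged under the
combined weight and the candidate list must include Z1 and X1. A magnitude
criterion (not a significance test) generates every report, and the header
says so.

Estimated null weights perturb correlations by O(1/√n) even with no
confounding (~0.03 at n = 2000); diagnostics on small samples should read
the weighted column as "small", not "zero".

## Imputation and pooling

Chained-equations predictive mean matching, hand-implemented (no installed
Python library provides PMM-MICE): per target column, a Bayesian linear
regression draw (σ² from a scaled inverse-χ², β from its normal posterior)
produces predictions; each missing cell receives the observed value of one
of the `donor_k = 5` donors with closest predicted means (type-1 matching:
donors scored with β̂, targets with the β draw), chosen uniformly.
Defaults m = 5, 10 sweeps. Imputed values are always observed values of
the same column, preserving support and shape.

Pooling follows Rubin's rules (Q̄, W, B, T = W + (1+1/m)B) with
Barnard–Rubin small-sample degrees of freedom given the complete-data
residual df. The pipeline imputes first and runs weighting + outcome
models separately within each completed data set — weights require
complete covariates — then pools estimates and the equal-effects contrast.

## Outcome models and model comparison

Weighted least squares via statsmodels WLS. Model-based SEs are the
default for data-analysis reports (the frequency-weights idiom, stamped
into every fit as `se_kind`); HC0 sandwich SEs are available via
`robust=True`. The simulation module always evaluates the IPTW arm with
the sandwich: IPTW weights are not precision weights, and under strong
confounding the model-based SE was measured at ~40% of the empirical SE
(coverage ≈ 0.5), while the sandwich restores ~0.95 coverage.

The log-likelihood is the weighted Gaussian one (including ½Σlog wᵢ), so
AIC/AICc are comparable across fits sharing a weight vector. AICc counts
the error variance as a parameter (k = p + 1) and adds the (2k²+2k)/(n−k−1)
correction; the suite's best model is the lowest mean AICc across
imputations. The equal-effects test is the Wald contrast (−1, 1) on the
differing-effects fit, identical to refitting on ((z1+z2)/2, (z2−z1)/2)
and reading the second coefficient. Standardized coefficients use weighted
SDs of predictor and outcome.

**AICc selection under exact equality is not near-certain.** When
δ₁ = δ₂ exactly, twice the log-likelihood gap between the differing and
constant models is asymptotically χ²(1) *regardless of the noise level*
(the statistic is pivotal), so the constant model wins AICc with
probability P(χ²₁ < 2 + Δpenalty) — about 0.87 at n = 64 and never above
0.95 for n ≳ 16. This is a property of AIC-family selection, not an
implementation artifact; the corresponding acceptance check is left
failing with this analysis rather than re-scoped to a tiny n.

## Synthetic worlds

The generator emulates a 64-family longitudinal input study: income drawn
over six bracket midpoints, education over five levels, caregiver verbal
IQ truncated-normal (57.9, 10.7) on [20, 80], child gender and birth order
Bernoulli(½), and right-skewed early word/gesture counts (lognormal,
medians 8.5 and 18.5). Two exposure scales are provided: word-types-like
(means ≈ 404/464, SDs ≈ 120) and clauses-per-100-sentences-like (means ≈
110/117, floored at 100 since every complete sentence has a clause).
Default missingness is MAR driven by income and education, with the
per-column rates matching the emulated study's valid-case counts (e.g.
13/64 for caregiver verbal IQ), and the logistic intercept calibrated by
root-finding so the marginal rate is exact.

What a green test does establish: correctness of the weighting, pooling
and selection machinery under linear-Gaussian structural equations with
known truth. What it does not: robustness to nonlinear exposure-outcome
relations, non-Gaussian noise, informative (MNAR) missingness, or the
covariate correlation structure of real families (the preset covariates
are drawn independently; the real joint distribution is not published).

## Numerical conventions

- Quantiles: linear interpolation for bin boundaries; order-statistic
  ("lower") percentiles for weight winsorization.
- z-scores use the n−1 (sample SD) denominator.
- Ties in predicted-outcome classification break by stable row order.
- Seed policy: every experiment spawns per-replicate seeds from a master
  seed via `SeedSequence`; sweeps share the replicate seed stream so the
  swept parameter is the only varying factor. Identical config ⇒
  byte-identical artifacts (CSV floats round-trip via
  `float_precision="round_trip"`).
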