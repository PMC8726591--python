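# quantiptw

Quantile-binned inverse-probability-of-treatment weighting (IPTW) for
**continuous, time-varying exposures** in small longitudinal cohorts, with
the full surrounding workflow: synthetic cohorts with known causal truth,
predictive-mean-matching multiple imputation, weighted outcome-model
comparison by AICc, balance diagnostics, Monte-Carlo validation, and
unmeasured-confounding sensitivity analysis.

## The problem

Developmental studies often measure a continuous "input" exposure at two
ages — say, the diversity of a parent's vocabulary when a child is 14 and
30 months old — and an outcome years later. Estimating the separate causal
effects of the earlier and the later exposure is hard because (a) family
background confounds both, and (b) the child's own mid-stream development
`x1` is a *time-varying confounder*: it responds to the earlier exposure
and shapes both the later exposure and the outcome. Regressing the outcome
on both exposures plus `x1` is wrong (it blocks part of the earlier
exposure's effect); ignoring `x1` is also wrong (it confounds the later
exposure).

## The method

The marginal structural model

```
Y_i = α + δ₁ Z₁ᵢ + δ₂ Z₂ᵢ + e_i
```

is estimated by weighted least squares, with weights that mimic a
randomized experiment over exposure *sequences*. Because the exposure is
continuous, each occasion is cut into K = 8 equal-frequency quantile bins;
a proportional-odds (cumulative-logit) model `P(bin ≤ j | x) =
logistic(θⱼ − x'β)` predicts bin membership from confounders, and each
subject gets the stabilized weight

```
wᵢ = P(bin = bᵢ) / P(bin = bᵢ | xᵢ)
```

for each occasion; the product w₁·w₂ weights the outcome model. Children
whose covariates made their observed input sequence unlikely are
up-weighted. Five outcome models span the scientific hypotheses (differing
effects, constant/cumulative effects with δ₁ = δ₂ = δ, earlier-only, and
the two "strong" single-occasion models), compared by small-sample AICc;
a Wald contrast tests δ₁ = δ₂. Missing data are handled by
predictive-mean-matching multiple imputation with Rubin's-rules pooling.

## Worked example

`examples/04_full_pipeline.py` runs the orchestrated analysis on the two
stated synthetic worlds (n = 64, five imputations each) and prints:

```
[vocab]
  best model by mean AICc : constant
  equal-effects test      : diff -0.001, p = 0.975
  calibrated profile gap  : +1.06 outcome SDs
[syntax]
  best model by mean AICc : later_strong
  equal-effects test      : diff +0.360, p = 0.004
  calibrated profile gap  : +0.67 outcome SDs
```

Reading: in the vocabulary world the generator gives earlier and later
input equal joint-intervention effects, and the analysis recovers that —
the equal-effects test retains the null (p = .975) and the parsimonious
constant-effects (cumulative input) model wins AICc. In the syntax world
the generator gives the two occasions opposite-signed effects; the
equal-effects test rejects (p = .004) and single-occasion/differing models
dominate. The calibrated gap translates the winning model's coefficients
into outcome standard deviations between a 25th- and a 75th-percentile
exposure profile.

The other examples each demonstrate one capability: cohort generation and
I/O (01), weighting and balance with covariate selection (02), imputation,
pooling and calibration (03), the Monte-Carlo estimator comparison and
bin-count sweep (05), and the unmeasured-confounder sensitivity grid (06).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch — both pipeline
worlds plus a reduced simulation comparing the naive and weighted
estimators against the generator truth — and writes the acceptance JSON.
All randomness derives from `--seed`.
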