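"""End-to-end analysis pipeline: impute, weight, check balance, fit the
outcome-model family, pool across imputations, calibrate and classify.

The pipeline is a plain function over a :class:`PipelineConfig`; every
artifact it writes is a CSV or JSON file stamped with a hash of the config,
and rerunning the same config yields byte-identical outputs.

Stage order is impute-first: the weight models need complete covariates, so
weights and fits are computed separately within each completed data set and
only the final estimates are pooled (Rubin's rules).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .balance import balance_report, select_covariates
from .imputation import pmm_impute, rubin_pool
from .outcome import fit_model_suite, test_equal_effects
from .synthetic import generate_cohort, read_cohort, truth_syntax, truth_vocab
from .weighting import iptw_weights

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("quantiptw.pipeline")

PRESETS = {"vocab": truth_vocab, "syntax": truth_syntax}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run depends on.

    Provide either ``input_csv`` (a cohort file written by
    :func:`quantiptw.synthetic.write_cohort`) or ``preset`` ("vocab" or
    "syntax") plus ``n`` to generate a cohort in-line.  When the covariate
    lists are ``None`` they are chosen by the greedy balance-driven
    selection loop.
    """

    outdir: str
    input_csv: str | None = None
    preset: str | None = "vocab"
    n: int = 64
    seed: int = 0
    z1: str = "z1"
    z2: str = "z2"
    y: str = "y"
    z1_covariates: tuple[str, ...] | None = None
    z2_covariates: tuple[str, ...] | None = None
    candidate_covariates: tuple[str, ...] = (
        "income",
        "education",
        "parent_verbal_iq",
        "child_gender",
        "birth_order",
        "child_word_types_14",
        "child_gesture_types_14",
    )
    k: int = 8
    m: int = 5
    donor_k: int = 5
    sweeps: int = 10
    balance_threshold: float = 0.1
    truncation: tuple[float, float] | None = None
    robust_se: bool = False
    n_top: int = 16
    n_bottom: int = 16

    def to_dict(self) -> dict:
        d = {}
        for f_ in self.__dataclass_fields__.values():
            v = getattr(self, f_.name)
            if isinstance(v, tuple):
                v = list(v)
            d[f_.name] = v
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_input(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        table, _ = read_cohort(config.input_csv)
    else:
        if config.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {config.preset!r}; choose from {sorted(PRESETS)}"
            )
        truth = PRESETS[config.preset](n=config.n, seed=config.seed)
        table, _ = generate_cohort(truth)
    return table


def _validate_columns(config: PipelineConfig, table: pd.DataFrame) -> None:
    needed = [config.z1, config.z2, config.y, *config.candidate_covariates]
    for group in (config.z1_covariates, config.z2_covariates):
        if group is not None:
            needed.extend(group)
    unknown = sorted(set(c for c in needed if c not in table.columns))
    if unknown:
        raise ValueError(f"config names columns absent from the cohort: {unknown}")


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Run the full analysis and return a manifest of artifacts."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = config.config_hash
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter() - t0
        if verbose:
            log.info("stage %s at %.2fs", name, timings[name])

    table = _load_input(config)
    _validate_columns(config, table)
    (outdir / "config.json").write_text(
        json.dumps({"config": config.to_dict(), "config_hash": h,
                    "quantiptw_version": __version__}, indent=2) + "\n"
    )
    _write_csv(table, outdir / "cohort.csv", h)
    stage("load")

    imps = pmm_impute(table, m=config.m, donor_k=config.donor_k,
                      sweeps=config.sweeps, seed=config.seed)
    stage("impute")

    # covariate selection on the first completed table (balance-driven greedy
    # loop) unless the config pins the lists
    first = imps.tables[0]
    if config.z1_covariates is None:
        z1_cov, _, _ = select_covariates(
            first, config.z1, list(config.candidate_covariates),
            k=config.k, threshold=config.balance_threshold,
        )
    else:
        z1_cov = list(config.z1_covariates)
    if config.z2_covariates is None:
        cand2 = [config.z1, "x1"] + list(config.candidate_covariates)
        w1_first, _, _ = _first_occasion_weights(first, config, z1_cov)
        z2_cov, _, _ = select_covariates(
            first, config.z2, cand2, k=config.k,
            threshold=config.balance_threshold, extra_weights=w1_first,
        )
        # the earlier exposure and the time-varying covariate always enter
        for forced in (config.z1, "x1"):
            if forced in first.columns and forced not in z2_cov:
                z2_cov.append(forced)
    else:
        z2_cov = list(config.z2_covariates)
    stage("select_covariates")

    fits_by_model: dict[str, list] = {}
    weights_rows = []
    balance_frames = []
    eq_tests = []
    for i, imp in enumerate(imps.tables):
        ws = iptw_weights(
            imp, config.z1, config.z2, z1_cov, z2_cov,
            k=config.k, truncation=config.truncation,
        )
        rep = balance_report(imp, ws, config.z1, list(config.candidate_covariates),
                             config.balance_threshold)
        bt = rep.table.assign(imputation=i, exposure=config.z1, ess=rep.ess)
        rep2 = balance_report(imp, ws, config.z2,
                              [config.z1, "x1"] + list(config.candidate_covariates),
                              config.balance_threshold)
        bt2 = rep2.table.assign(imputation=i, exposure=config.z2, ess=rep2.ess)
        balance_frames.extend([bt, bt2])
        weights_rows.append(
            pd.DataFrame({"imputation": i, "subject": np.arange(len(imp)),
                          "w1": ws.w1, "w2": ws.w2, "w": ws.w})
        )
        suite = fit_model_suite(imp, config.z1, config.z2, config.y, ws,
                                robust=config.robust_se)
        for kind, fit in suite.items():
            fits_by_model.setdefault(kind, []).append(fit)
        eq_tests.append(test_equal_effects(suite["differing"]))
    stage("weight_fit")

    pooled_rows = []
    for kind, fits in fits_by_model.items():
        mean_aicc = float(np.mean([f.aicc for f in fits]))
        for pred in fits[0].params.index:
            if pred == "const":
                continue
            est = [float(f.params[pred]) for f in fits]
            ses = [float(f.ses[pred]) for f in fits]
            pf = rubin_pool(est, ses, df_complete=fits[0].df_resid)
            std = float(np.mean([f.std_coefs[pred] for f in fits]))
            pooled_rows.append(
                {"model": kind, "predictor": pred, "estimate": pf.estimate,
                 "beta_std": std, "ci_lo": pf.ci[0], "ci_hi": pf.ci[1],
                 "se": pf.se, "t": pf.estimate / pf.se, "nominal_p": pf.p,
                 "df": pf.df, "aicc": mean_aicc, "se_kind": fits[0].se_kind}
            )
    pooled = pd.DataFrame(pooled_rows)
    eq_pool = rubin_pool(
        [e["estimate"] for e in eq_tests], [e["se"] for e in eq_tests],
        df_complete=fits_by_model["differing"][0].df_resid,
    )
    # the earlier-only model is fit under w1-only weights; its likelihood is
    # not on the same scale as the combined-weight fits, so it never enters
    # the AICc comparison (it answers the "apparent effect" question instead)
    comparable = [k for k in fits_by_model if k != "earlier_only_weighted_baseline"]
    best_model = min(
        comparable, key=lambda kind: float(np.mean([f.aicc for f in fits_by_model[kind]]))
    )
    stage("pool")

    # calibration: 25th vs 75th percentile exposure profiles under the best
    # model's pooled coefficients, in outcome-SD units
    stacked = pd.concat(imps.tables)
    q = {
        name: (float(np.percentile(stacked[name], 25)),
               float(np.percentile(stacked[name], 75)))
        for name in (config.z1, config.z2)
    }
    sd_y = float(np.std(stacked[config.y], ddof=1))
    best_fits = fits_by_model[best_model]
    cal_low, cal_high = [], []
    for f in best_fits:
        from .outcome import calibrate_effect

        c = calibrate_effect(
            f,
            (q[config.z1][0], q[config.z2][0]),
            (q[config.z1][1], q[config.z2][1]),
            sd_y,
        )
        cal_low.append(c["predicted_low"])
        cal_high.append(c["predicted_high"])
    calibration = {
        "model": best_model,
        "profile_low": [q[config.z1][0], q[config.z2][0]],
        "profile_high": [q[config.z1][1], q[config.z2][1]],
        "predicted_low": float(np.mean(cal_low)),
        "predicted_high": float(np.mean(cal_high)),
        "sd_outcome": sd_y,
        "standardized_difference": float(
            (np.mean(cal_high) - np.mean(cal_low)) / sd_y
        ),
    }

    # classification by imputation-averaged predicted outcome of best model
    pred_best = np.mean(
        [
            [_predict_one(f, a, b) for a, b in
             zip(imp[config.z1], imp[config.z2])]
            for f, imp in zip(best_fits, imps.tables)
        ],
        axis=0,
    )
    n = len(table)
    order = np.argsort(pred_best, kind="stable")
    labels = np.array(["mid"] * n, dtype=object)
    labels[order[: config.n_bottom]] = "low"
    labels[order[n - config.n_top:]] = "high"
    classification = pd.DataFrame(
        {
            "subject": np.arange(n),
            config.z1: np.mean([imp[config.z1] for imp in imps.tables], axis=0),
            config.z2: np.mean([imp[config.z2] for imp in imps.tables], axis=0),
            "predicted": pred_best,
            "label": labels,
        }
    )
    stage("calibrate_classify")

    _write_csv(pd.concat(weights_rows, ignore_index=True), outdir / "weights.csv", h)
    _write_csv(pd.concat(balance_frames, ignore_index=True), outdir / "balance.csv", h)
    _write_csv(pooled, outdir / "pooled_fits.csv", h)
    _write_csv(classification, outdir / "classification.csv", h)
    report = {
        "config_hash": h,
        "quantiptw_version": __version__,
        "seed": config.seed,
        "z1_covariates": z1_cov,
        "z2_covariates": z2_cov,
        "best_model": best_model,
        "equal_effects_test": {
            "estimate": eq_pool.estimate, "se": eq_pool.se,
            "ci": list(eq_pool.ci), "p": eq_pool.p,
        },
        "calibration": calibration,
        "mean_aicc": {
            kind: float(np.mean([f.aicc for f in fits]))
            for kind, fits in fits_by_model.items()
        },
        "stage_seconds": timings,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {
        "config_hash": h,
        "artifacts": sorted(
            str(p.name) for p in outdir.iterdir() if p.suffix in (".csv", ".json")
        ),
        **report,
    }
    return manifest


def _first_occasion_weights(table, config, z1_cov):
    from .weighting import exposure_weights

    return exposure_weights(table, config.z1, z1_cov, k=config.k)


def _predict_one(fit, z1v: float, z2v: float) -> float:
    from .outcome import _predict_profile

    return _predict_profile(fit, (z1v, z2v))
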