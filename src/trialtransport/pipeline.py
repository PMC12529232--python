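"""End-to-end transported-effect analysis.

For each target-population survey year: harmonize and stack the trial
and survey records, multiply impute missing covariates (trial and
survey separately), fit the selection model on each completed stacked
dataset, compute inverse-odds-of-selection weights, fit the weighted
outcome model, and pool the per-imputation arm log-odds-ratios with
Rubin's rules.  The within-trial (unweighted) estimate is reported
alongside.  Sensitivity modes: complete-case (no imputation, rows with
any missing analysis variable dropped) and England-only (trial schools
from Wales excluded before analysis).

Every stage logs record-count deltas; a failure in one year is captured
as a structured error and the remaining years proceed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .effects import EffectEstimate, fit_transported_effect, fit_trial_effect
from .harmonize import (SELECTION_COVARIATES, STRATIFICATION_VARIABLES,
                        collapse_unsupported_levels, read_records, stack_datasets,
                        validate_records, write_records)
from .missing import impute, monte_carlo_error_check, pool_rubin
from .synthetic import (GeneratorConfig, SURVEY_YEARS, make_default_config,
                        generate_survey, generate_trial, save_config)
from .weights import (fit_selection_model, inverse_odds_weights, positivity_report,
                      predict_selection_prob, predict_selection_prob_conditional)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "TransportReport", "run_transport",
           "make_fixture_bundle", "write_report"]


@dataclass
class AnalysisConfig:
    """Configuration surface of one transported analysis."""

    covariates: list = field(default_factory=lambda: list(SELECTION_COVARIATES))
    strat_vars: list = field(default_factory=lambda: list(STRATIFICATION_VARIABLES))
    years: list = field(default_factory=lambda: list(SURVEY_YEARS))
    m: int = 20
    seed: int = 0
    weight_truncation: tuple | None = None
    weight_normalize: bool = False
    weight_scaling: str = "mean_one"
    prediction_mode: str = "marginal"   # how school effects enter p_i
    complete_case: bool = False
    england_only: bool = False
    mi_method: str = "chained_equations"
    n_quad: int = 15

    def validate(self) -> None:
        known = set(SELECTION_COVARIATES) | set(STRATIFICATION_VARIABLES)
        unknown = [v for v in list(self.covariates) + list(self.strat_vars) if v not in known]
        if unknown:
            raise ValueError(f"variables not in the harmonized schema: {unknown}")
        if self.m < 2 and not self.complete_case:
            raise ValueError("m must be >= 2 unless running complete-case")
        if self.prediction_mode not in ("marginal", "conditional"):
            raise ValueError(f"unknown prediction mode {self.prediction_mode!r}")


@dataclass
class TransportReport:
    """Per-year transported estimates plus the within-trial estimate."""

    trial_estimate: EffectEstimate | None
    year_results: dict
    config: AnalysisConfig
    provenance: dict

    def forest_table(self) -> pd.DataFrame:
        rows = []
        if self.trial_estimate is not None:
            e = self.trial_estimate
            rows.append({"analysis": "trial", "year": "", "or": e.or_, "ci_low": e.ci_low,
                         "ci_high": e.ci_high, "ci_ratio": e.ci_ratio, "n": e.n,
                         "n_schools": e.n_schools, "weighted": e.weighted})
        for year in sorted(self.year_results):
            res = self.year_results[year]
            if res.get("error"):
                rows.append({"analysis": "transported", "year": year, "or": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "ci_ratio": np.nan,
                             "n": np.nan, "n_schools": np.nan, "weighted": True})
                continue
            e = res["estimate"]
            rows.append({"analysis": "transported", "year": year, "or": e.or_,
                         "ci_low": e.ci_low, "ci_high": e.ci_high, "ci_ratio": e.ci_ratio,
                         "n": e.n, "n_schools": e.n_schools, "weighted": e.weighted})
        return pd.DataFrame(rows)


def _load(records) -> pd.DataFrame:
    if isinstance(records, (str, Path)):
        return read_records(records)
    return validate_records(records)


def _complete_case_filter(df: pd.DataFrame, variables: list[str], label: str) -> pd.DataFrame:
    keep = df[variables].notna().all(axis=1)
    logger.info("complete case (%s): kept %d of %d rows", label, int(keep.sum()), len(df))
    return df.loc[keep].reset_index(drop=True)


def _one_weighted_analysis(trial_df, survey_df, year, config: AnalysisConfig):
    """Stack, fit selection model, weight, fit transported effect."""
    trial_df, survey_df, merges = collapse_unsupported_levels(
        trial_df, survey_df, config.covariates)
    stacked = stack_datasets(trial_df, survey_df, year)
    sel = fit_selection_model(stacked, config.covariates, n_quad=config.n_quad)
    if config.prediction_mode == "conditional":
        p = predict_selection_prob_conditional(sel, stacked)
    else:
        p = predict_selection_prob(sel, stacked.records, mode="marginal")
    ws = inverse_odds_weights(p, stacked.S == 1, year=year,
                              truncation=config.weight_truncation,
                              normalize=config.weight_normalize)
    trial_rows = stacked.records[stacked.records["S"] == 1].reset_index(drop=True)
    est = fit_transported_effect(trial_rows, ws, config.strat_vars,
                                 weight_scaling=config.weight_scaling,
                                 n_quad=config.n_quad, year=year)
    pos = positivity_report(ws, stacked, config.covariates)
    pos["collapsed_levels"] = [list(m) for m in merges]
    return est, ws, pos


def run_transport(trial, surveys: dict, config: AnalysisConfig | None = None) -> TransportReport:
    """Run the full transported-effect analysis.

    Parameters
    ----------
    trial : DataFrame or CSV path of harmonized trial records.
    surveys : mapping year -> DataFrame or CSV path of survey records.
    config : analysis options; defaults to the standard specification.
    """
    config = config or AnalysisConfig()
    config.validate()
    trial_df = _load(trial)
    if config.england_only:
        n0 = len(trial_df)
        trial_df = trial_df[trial_df["country"] == "england"].reset_index(drop=True)
        logger.info("england_only: %d of %d trial rows retained", len(trial_df), n0)

    analysis_vars = list(config.covariates) + ["outcome_weekly"]
    trial_cc = _complete_case_filter(trial_df, analysis_vars, "trial")
    if config.complete_case:
        trial_used = trial_cc
        trial_imps = None
    elif trial_df[analysis_vars].isna().any().any():
        trial_imps = impute(trial_df, m=config.m, seed=config.seed,
                            method=config.mi_method, predictors=config.covariates)
        trial_used = None
    else:
        trial_imps = None
        trial_used = trial_df

    try:
        trial_estimate = fit_trial_effect(trial_cc, config.strat_vars, n_quad=config.n_quad)
    except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
        logger.error("trial effect failed: %s", exc)
        trial_estimate = None

    year_results: dict = {}
    for year in config.years:
        if year not in surveys:
            year_results[year] = {"error": f"no survey data supplied for {year}"}
            continue
        try:
            survey_df = _load(surveys[year])
            year_results[year] = _run_year(trial_used, trial_imps, survey_df, year, config)
        except Exception as exc:  # noqa: BLE001
            logger.error("year %s failed: %s", year, exc)
            year_results[year] = {"error": f"{type(exc).__name__}: {exc}"}

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    return TransportReport(trial_estimate=trial_estimate, year_results=year_results,
                           config=config, provenance=provenance)


def _run_year(trial_used, trial_imps, survey_df, year, config: AnalysisConfig) -> dict:
    analysis_vars = list(config.covariates)
    if config.complete_case:
        survey_cc = _complete_case_filter(survey_df, analysis_vars, f"survey {year}")
        est, ws, pos = _one_weighted_analysis(trial_used, survey_cc, year, config)
        return {"estimate": est, "positivity": pos, "n_imputations": 0,
                "ess": ws.ess, "error": None}

    survey_missing = survey_df[analysis_vars].isna().any().any()
    if trial_imps is None and not survey_missing:
        est, ws, pos = _one_weighted_analysis(trial_used, survey_df, year, config)
        return {"estimate": est, "positivity": pos, "n_imputations": 0,
                "ess": ws.ess, "error": None}

    survey_imps = (impute(survey_df, m=config.m, seed=config.seed + year,
                          method=config.mi_method, predictors=config.covariates)
                   if survey_missing else None)
    log_ors, variances = [], []
    pos = ess = None
    m = config.m
    for j in range(m):
        tr_j = trial_imps.completed_datasets[j] if trial_imps is not None else trial_used
        sv_j = survey_imps.completed_datasets[j] if survey_imps is not None else survey_df
        est_j, ws_j, pos_j = _one_weighted_analysis(tr_j, sv_j, year, config)
        log_ors.append(est_j.log_or)
        variances.append(est_j.se ** 2)
        if j == 0:
            pos, ess, template = pos_j, ws_j.ess, est_j
    pooled = pool_rubin(log_ors, variances)
    mc = monte_carlo_error_check(pooled)
    z = stats.t.ppf(0.975, pooled.df) if np.isfinite(pooled.df) else 1.959963984540054
    est = EffectEstimate.from_wald(
        pooled.qbar, float(np.sqrt(pooled.total_var)), z=float(z),
        n=template.n, n_schools=template.n_schools, weighted=True, year=year,
        sigma_u=template.sigma_u,
    )
    return {"estimate": est, "positivity": pos, "n_imputations": m,
            "ess": ess, "pooled": pooled, "monte_carlo": mc, "error": None}


# ---------------------------------------------------------------------------
# fixture bundle

def make_fixture_bundle(out_dir, seed: int = 0, scale: float = 1.0,
                        config: GeneratorConfig | None = None) -> dict:
    """Write a synthetic trial + five survey CSVs plus the generator config.

    At ``scale=1`` the files carry the published sample sizes (trial
    8756; surveys 3958 / 3377 / 3145 / 4874 / 3587).  ``scale`` shrinks
    every count proportionally for quick runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or make_default_config(seed)
    if scale != 1.0:
        cfg.trial_arm_student_counts = {k: max(20, round(v * scale))
                                        for k, v in cfg.trial_arm_student_counts.items()}
        n_int = max(3, round(cfg.trial_arm_school_counts["intervention"] * scale))
        n_con = max(3, round(cfg.trial_arm_school_counts["control"] * scale))
        cfg.trial_arm_school_counts = {"intervention": n_int, "control": n_con}
        cfg.trial_n_schools = n_int + n_con
        for spec in cfg.survey_specs.values():
            spec.n_students = max(50, round(spec.n_students * scale))
            spec.n_schools = max(4, round(spec.n_schools * scale))
    paths = {}
    trial = generate_trial(cfg, seed)
    trial_path = out / "trial.csv"
    write_records(trial, trial_path)
    paths["trial"] = trial_path
    for year in cfg.survey_specs:
        sv = generate_survey(cfg, year, seed)
        p = out / f"survey_{year}.csv"
        write_records(sv.drop(columns=["routed"]), p)
        paths[year] = p
    cfg_path = out / "generator_config.yaml"
    save_config(cfg, cfg_path)
    paths["config"] = cfg_path
    return paths


# ---------------------------------------------------------------------------
# report output

def _jsonable(obj):
    if isinstance(obj, EffectEstimate):
        return obj.to_dict()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return obj


def write_report(report: TransportReport, out_dir) -> dict:
    """Write the JSON report and the CSV forest table; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "trial_estimate": _jsonable(report.trial_estimate),
        "year_results": _jsonable(report.year_results),
        "config": _jsonable(report.config),
        "provenance": report.provenance,
        "report_format_version": 1,
    }
    json_path = out / "transport_report.json"
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    csv_path = out / "forest_table.csv"
    report.forest_table().to_csv(csv_path, index=False)
    return {"json": json_path, "forest": csv_path}
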