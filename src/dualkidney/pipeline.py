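"""End-to-end pipeline: one structured config in, all result tables out.

Stages run in analysis order — registry (generated or ingested) -> cohort
filtering and imputation -> propensity matching -> survival estimation ->
counterfactual projection -> waitlist microsimulation — and every table is
written as CSV together with a run manifest (config digest, per-stage seeds,
output digests) that makes reruns byte-checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, reference
from .cohort_pipeline import demographic_table, filter_cohort, impute_missing
from .counterfactual_projection import (ProjectionInputs, interpolate_survival,
                                        project_dual_to_single)
from .propensity_matching import (DEFAULT_PS_COVARIATES, balance_table,
                                  fit_propensity, select_matching_ratio)
from .survival_models import (DEFAULT_ADJUSTMENT_COVARIATES, ENDPOINTS, cox_fit,
                              km_by_group, log_rank_test, survival_table)
from .synthetic_registry import (GeneratorConfig, generate_registry,
                                 generate_waitlist_schedule, read_registry,
                                 validate_registry)
from .waitlist_microsim import SimConfig, compare_pathways

log = logging.getLogger("dualkidney")

TABLE1_VARIABLES = DEFAULT_PS_COVARIATES

REQUIRED_COLUMNS = [
    "id", "group", "recipient_age", "living_donor", "en_bloc", "kdri",
    "time_death", "event_death", "time_graftfail", "event_graftfail",
]

OUTCOME_VARIABLES = ["los_days", "dgf", "rejection_6m", "rejection_1y",
                     "creatinine_1y"]

DEFAULT_CONFIG = {
    # demo scale keeps the real cohort's ~100:1 control-to-treated pool ratio
    "registry": {"n_dual": 300, "n_single": 30000, "seed": 11},
    "matching": {"ratios": [1, 2, 3], "threshold": 0.1, "seed": 12,
                 "covariates": None},
    "survival": {"query_years": [1, 2, 4, 6]},
    "projection": {"horizon_years": 5.0, "use_reference_inputs": True},
    "microsim": {"n_candidates": 20000, "seed": 13,
                 "schedule": {"seed": 14, "base_p_transplant": 0.15,
                              "base_p_death": 0.05, "dual_fraction": 0.01,
                              "n_years": 11, "jitter": 0.0}},
}


class SchemaError(ValueError):
    """Ingested registry does not carry the required columns."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    cfg["microsim"]["schedule"] = dict(DEFAULT_CONFIG["microsim"]["schedule"])
    for section, values in user.items():
        if section == "ingest":
            cfg["ingest"] = values
        elif isinstance(values, dict):
            for k, v in values.items():
                if k == "schedule" and isinstance(v, dict):
                    cfg["microsim"]["schedule"].update(v)
                else:
                    cfg.setdefault(section, {})[k] = v
        else:
            cfg[section] = values
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def _load_registry(cfg: dict) -> pd.DataFrame:
    if cfg.get("ingest"):
        df = read_registry(cfg["ingest"])
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"ingested registry missing column(s): {missing}")
        return df
    gen = GeneratorConfig(**cfg["registry"])
    df = generate_registry(gen)
    validate_registry(df, gen.max_followup_years)
    return df


def run_pipeline(config_path, out_dir) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {
        "config_hash": config_hash,
        "seeds": {"registry": cfg["registry"].get("seed"),
                  "matching": cfg["matching"].get("seed"),
                  "microsim": cfg["microsim"].get("seed"),
                  "schedule": cfg["microsim"]["schedule"].get("seed")},
        "versions": {"dualkidney": __version__},
        "timestamps": {"start": datetime.now(timezone.utc).isoformat()},
        "stages": {},
    }

    stage = "registry"
    try:
        registry = _load_registry(cfg)
        manifest["stages"]["registry"] = {"n_records": len(registry)}
        log.info("registry: %d records", len(registry))

        stage = "cohort"
        cohort, report = filter_cohort(registry)
        cohort = impute_missing(cohort)
        manifest["stages"]["cohort"] = {
            "n_input": report.n_input,
            "n_excluded_by_rule": report.n_excluded_by_rule,
            "n_output": report.n_output,
        }
        log.info("cohort: %d -> %d records", report.n_input, report.n_output)
        _write(demographic_table(cohort, TABLE1_VARIABLES), out / "table1_demographics.csv")

        stage = "matching"
        mcfg = cfg["matching"]
        covariates = mcfg.get("covariates") or DEFAULT_PS_COVARIATES
        model = fit_propensity(cohort, covariates)
        cohort_matched = select_matching_ratio(
            cohort, covariates, ratios=tuple(mcfg["ratios"]),
            threshold=mcfg["threshold"], seed=mcfg["seed"], model=model)
        matched = cohort_matched.subset(cohort)
        manifest["stages"]["matching"] = {
            "ratio": cohort_matched.ratio,
            "balanced": cohort_matched.balanced,
            "n_treated": cohort_matched.n_treated,
            "n_control": cohort_matched.n_control,
            "candidate_max_abs_smd": cohort_matched.candidate_balance,
        }
        _write(cohort_matched.pairs_frame(), out / "matched_pairs.csv")
        _write(balance_table(cohort, cohort_matched, covariates),
               out / "balance_table.csv")

        stage = "survival"
        query_years = cfg["survival"]["query_years"]
        cox_rows = []
        km_single_dcg = None
        for i, (name, endpoint) in enumerate(ENDPOINTS.items(), start=2):
            fits = km_by_group(matched, endpoint)
            tab = survival_table(fits, query_years)
            ta, ea = endpoint.extract(matched[matched["group"] == "dual"])
            tb, eb = endpoint.extract(matched[matched["group"] == "single"])
            stat, p, _ = log_rank_test(ta, ea, tb, eb)
            tab["logrank_statistic"] = stat
            tab["logrank_p"] = p
            _write(tab, out / f"table{i}_{name}.csv")
            if name == "death_censored_graft":
                km_single_dcg = fits["single"]
            for mode, covs in (("univariable", []),
                               ("multivariable", DEFAULT_ADJUSTMENT_COVARIATES)):
                fit = cox_fit(matched, endpoint, covs)
                row = fit.summary().iloc[0]  # group term
                cox_rows.append({"endpoint": name, "model": mode,
                                 "term": row["term"], "hr": row["hr"],
                                 "ci_low": row["ci_low"], "ci_high": row["ci_high"],
                                 "p_value": row["p_value"]})
        _write(pd.DataFrame(cox_rows), out / "table5_cox.csv")
        _write(demographic_table(matched, OUTCOME_VARIABLES),
               out / "table6_outcomes.csv")

        stage = "projection"
        pcfg = cfg["projection"]
        horizon = float(pcfg["horizon_years"])
        if pcfg.get("use_reference_inputs", True):
            inputs = reference.reference_projection_inputs(horizon)
        else:
            hr_row = [r for r in cox_rows
                      if r["endpoint"] == "death_censored_graft"
                      and r["model"] == "multivariable"][0]
            inputs = ProjectionInputs(
                n_single=int(pcfg.get("n_single",
                                      reference.TRANSPLANT_VOLUMES_2023["single"])),
                n_dual=int(pcfg.get("n_dual",
                                    reference.TRANSPLANT_VOLUMES_2023["dual"])),
                hr_dual_vs_single=hr_row["hr"],
                hr_ci95=(hr_row["ci_low"], hr_row["ci_high"]),
                horizon_years=horizon,
                single_survival_at_horizon=interpolate_survival(
                    km_single_dcg, horizon),
            )
        projection = project_dual_to_single(inputs)
        _write(projection.to_frame(), out / "projection.csv")
        manifest["stages"]["projection"] = {
            "percent_increase": projection.percent_increase}

        stage = "microsim"
        scfg = cfg["microsim"]
        schedule = generate_waitlist_schedule(**scfg["schedule"])
        schedule.to_yaml(out / "waitlist_schedule.yaml")
        comparison = compare_pathways(SimConfig(
            schedule=schedule, n_candidates=scfg["n_candidates"],
            seed=scfg["seed"]))
        per_year = comparison.path1.per_year.merge(
            comparison.path2.per_year, on="year", suffixes=("_path1", "_path2"))
        _write(per_year, out / "microsim_per_year.csv")
        manifest["stages"]["microsim"] = {
            "waitlist_deaths_path1": comparison.path1.total_waitlist_deaths,
            "waitlist_deaths_path2": comparison.path2.total_waitlist_deaths,
            "relative_death_reduction_pct": round(
                comparison.relative_death_reduction, 1),
            "additional_transplants": comparison.additional_transplants,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise StageError(stage, exc) from exc

    manifest["timestamps"]["end"] = datetime.now(timezone.utc).isoformat()
    manifest["output_digests"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
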