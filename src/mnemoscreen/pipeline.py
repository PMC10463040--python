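"""End-to-end orchestration of the mnemonic-construction procedure.

The five-step procedure, run from a single config:

1. profile every symptom on the original (complete-case) data;
2. select candidate symptoms with OR above the threshold;
3. enumerate anchored composite rules over the qualifying secondaries;
4. profile every rule on the original and (optionally) multiply-imputed data;
5. rank the rules, then bootstrap-validate and stratify the top rule.

Each stage writes a plain TSV + JSON report; a machine-readable run summary
records every configurable decision (evaluability mode, CI methods, m, B,
seeds, software versions) so a run is auditable and reproducible:
stage outputs are pure functions of (input data, config, seed).
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__
from .cohort import SYMPTOMS, CohortTable, read_cohort
from .imputation import ImputationConfig, PooledProfile, impute, pool_profiles
from .metrics import (
    STATISTICS,
    DiagnosticProfile,
    cross_tabulate,
    diagnostic_profile,
    profiles_to_frame,
)
from .rules import (
    CompositeRule,
    enumerate_mnemonics,
    rank_mnemonics,
    select_candidate_symptoms,
)
from .synthetic import default_cohort_params, generate, make_reference_cohort
from .validation import bootstrap_validate, compare_strata, stratified_profiles

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("mnemoscreen")

DEFAULT_STRATA = ("sex", "age_group", "smoking", "bmi_group", "DM", "hypertension")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``input`` is a cohort CSV path, ``"reference"`` (the packaged
    reference-margins cohort) or ``"synthetic"`` (generate from the default
    parameters at the run seed).  One top-level ``seed`` deterministically
    spawns independent substreams for generation, imputation and bootstrap.
    """

    input: str = "reference"
    schema: dict[str, str] | None = None
    symptoms: tuple[str, ...] = SYMPTOMS
    anchor: str = "chest_pain"
    or_threshold: float = 1.0
    min_size: int | None = None  # default: n_candidates - 1
    max_size: int | None = None
    specificity_floor: float = 0.5
    rule_list: tuple[tuple[str, ...], ...] | None = None  # explicit override
    strict_evaluability: bool = False
    imputation_enabled: bool = True
    imputation_m: int = 5
    imputation_method: str = "em_bootstrap_latent_normal"
    bootstrap_enabled: bool = True
    bootstrap_B: int = 1000
    strata: tuple[str, ...] = DEFAULT_STRATA
    outdir: str = "mnemoscreen_out"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("symptoms", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("rule_list"):
            raw["rule_list"] = tuple(tuple(r) for r in raw["rule_list"])
        return cls(**raw)


def _est_json(e) -> dict[str, float]:
    return {"point": e.point, "lower": e.lower, "upper": e.upper, "method": e.method}


def _profile_json(p: DiagnosticProfile | PooledProfile) -> dict[str, Any]:
    out: dict[str, Any] = {s: _est_json(p.statistic(s)) for s in STATISTICS}
    out["n"] = p.n_used
    return out


def _write_report(outdir: Path, name: str, frame: pd.DataFrame, payload: Any) -> None:
    frame.to_csv(outdir / f"{name}.tsv", sep="\t")
    with open(outdir / f"{name}.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def _load_cohort(config: PipelineConfig, seed: int | None) -> CohortTable:
    if config.input == "reference":
        return make_reference_cohort()
    if config.input == "synthetic":
        return generate(default_cohort_params(), seed=seed)
    path = Path(config.input)
    if not path.exists():
        raise PipelineError("load", f"input file {path} does not exist")
    return read_cohort(path, schema=config.schema)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns (and writes) the run summary."""
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(("generate", "imputation", "bootstrap"), ss.spawn(3))
    }
    summary: dict[str, Any] = {
        "package": {"name": "mnemoscreen", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seeds": seeds,
        "decisions": {
            "evaluability": "strict" if config.strict_evaluability else "witness",
            "ci_proportions": "wilson",
            "ci_ratios": "woolf",
            "or_estimator": "cross_product",
            "pooling": "rubin",
            "imputation_m": config.imputation_m,
            "bootstrap_B": config.bootstrap_B,
        },
        "stages": {},
    }

    # -- load ---------------------------------------------------------------
    try:
        cohort = _load_cohort(config, seeds["generate"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    summary["stages"]["load"] = {
        "rows": len(cohort), "acs": cohort.n_positive,
        "provenance": cohort.provenance,
    }

    # -- stage 1: per-symptom profiles (original) ---------------------------
    try:
        symptom_profiles: dict[str, DiagnosticProfile] = {}
        for s in config.symptoms:
            symptom_profiles[s] = diagnostic_profile(cross_tabulate(cohort, s))
        _write_report(outdir, "symptom_profiles_original",
                      profiles_to_frame(symptom_profiles),
                      {s: _profile_json(p) for s, p in symptom_profiles.items()})
    except Exception as exc:
        raise PipelineError("symptom_profiles", str(exc)) from exc
    summary["stages"]["symptom_profiles"] = {"n_symptoms": len(symptom_profiles)}

    # -- multiple imputation ------------------------------------------------
    completed = None
    if config.imputation_enabled:
        try:
            mi_cfg = ImputationConfig(
                m=config.imputation_m, seed=seeds["imputation"],
                method=config.imputation_method,  # type: ignore[arg-type]
            )
            completed = impute(cohort, mi_cfg)
            pooled_symptoms = {
                s: pool_profiles([
                    diagnostic_profile(cross_tabulate(ct, s)) for ct in completed
                ])
                for s in config.symptoms
            }
            _write_report(outdir, "symptom_profiles_imputed",
                          profiles_to_frame(pooled_symptoms),
                          {s: _profile_json(p) for s, p in pooled_symptoms.items()})
            summary["stages"]["imputation"] = {"m": mi_cfg.m, "method": mi_cfg.method}
        except Exception as exc:
            raise PipelineError("imputation", str(exc)) from exc

    # -- candidate selection ------------------------------------------------
    try:
        candidates = select_candidate_symptoms(symptom_profiles, config.or_threshold)
    except Exception as exc:
        raise PipelineError("candidate_selection", str(exc)) from exc
    summary["stages"]["candidate_selection"] = {
        "threshold": config.or_threshold, "selected": candidates,
    }

    # -- rule enumeration ---------------------------------------------------
    try:
        if config.rule_list is not None:
            rules = [CompositeRule(config.anchor, secs,
                                   strict=config.strict_evaluability)
                     for secs in config.rule_list]
        else:
            secondaries = [s for s in candidates if s != config.anchor]
            if not secondaries:
                raise ValueError("no candidate secondaries above the OR threshold")
            min_size = (config.min_size if config.min_size is not None
                        else max(1, len(secondaries) - 1))
            rules = enumerate_mnemonics(
                config.anchor, secondaries, min_size,
                config.max_size, strict=config.strict_evaluability,
            )
    except Exception as exc:
        raise PipelineError("rule_enumeration", str(exc)) from exc
    summary["stages"]["rule_enumeration"] = {"n_rules": len(rules),
                                             "rules": [r.label for r in rules]}

    # -- rule profiles + ranking -------------------------------------------
    try:
        evaluated = [(r, diagnostic_profile(cross_tabulate(cohort, r)))
                     for r in rules]
        _write_report(outdir, "rule_profiles_original",
                      profiles_to_frame({r.label: p for r, p in evaluated}),
                      {r.label: _profile_json(p) for r, p in evaluated})
        if completed is not None:
            pooled_rules = {
                r.label: pool_profiles([
                    diagnostic_profile(cross_tabulate(ct, r)) for ct in completed
                ])
                for r in rules
            }
            _write_report(outdir, "rule_profiles_imputed",
                          profiles_to_frame(pooled_rules),
                          {lbl: _profile_json(p) for lbl, p in pooled_rules.items()})
        ranking = rank_mnemonics(evaluated, config.specificity_floor,
                                 config.or_threshold)
    except Exception as exc:
        raise PipelineError("ranking", str(exc)) from exc
    summary["stages"]["ranking"] = {
        "specificity_floor": config.specificity_floor,
        "order": [r.label for r, _ in ranking.entries],
        "all_excluded": ranking.all_excluded,
    }
    if ranking.all_excluded:
        log.warning("every rule fell below the specificity floor; stopping")
        _finish(summary, outdir, t0)
        return summary
    top_rule, top_profile = ranking.entries[0]
    summary["top_rule"] = {"label": top_rule.label,
                           "profile": _profile_json(top_profile)}

    # -- bootstrap internal validation -------------------------------------
    if config.bootstrap_enabled:
        try:
            report = bootstrap_validate(cohort, top_rule, B=config.bootstrap_B,
                                        seed=seeds["bootstrap"])
            frame = pd.DataFrame({
                stat: {
                    "original": bs.original, "boot_mean": bs.boot_mean,
                    "boot_median": bs.boot_median, "ci_lower": bs.ci_lower,
                    "ci_upper": bs.ci_upper, "bias": bs.bias,
                }
                for stat, bs in report.statistics.items()
            }).T
            payload = {stat: dict(frame.loc[stat]) for stat in frame.index}
            _write_report(outdir, "bootstrap_validation", frame, payload)
            summary["stages"]["bootstrap"] = {
                "B": report.B, "n_redrawn": report.n_redrawn,
                "or_boot_mean": report.statistic("odds_ratio").boot_mean,
            }
        except Exception as exc:
            raise PipelineError("bootstrap", str(exc)) from exc

    # -- stratified analysis ------------------------------------------------
    strata_payload: dict[str, Any] = {}
    for stratum in config.strata:
        if stratum not in cohort.df.columns:
            continue
        try:
            results = stratified_profiles(cohort, top_rule, stratum)
        except ValueError:
            continue
        except Exception as exc:
            raise PipelineError("stratified", str(exc)) from exc
        entry: dict[str, Any] = {"levels": {}}
        estimable = [(lvl, r) for lvl, r in results.items() if r.profile is not None]
        for lvl, r in results.items():
            entry["levels"][str(lvl)] = (
                _profile_json(r.profile) if r.profile is not None
                else {"not_estimable": r.reason}
            )
        if len(estimable) == 2:
            (la, ra), (lb, rb) = estimable
            entry["comparison"] = {
                stat: {
                    "difference_transformed": cmpres.difference,
                    "z": cmpres.z, "p": cmpres.p, "ci_overlap": cmpres.ci_overlap,
                }
                for stat in ("odds_ratio", "sensitivity", "specificity")
                for cmpres in [compare_strata(ra.profile, rb.profile, stat,
                                              str(la), str(lb))]
            }
        strata_payload[stratum] = entry
    if strata_payload:
        with open(outdir / "stratified_analysis.json", "w") as fh:
            json.dump(strata_payload, fh, indent=2, sort_keys=True)
        summary["stages"]["stratified"] = {"strata": sorted(strata_payload)}

    _finish(summary, outdir, t0)
    return summary


def _finish(summary: dict[str, Any], outdir: Path, t0: float) -> None:
    log.info("pipeline done in %.1fs", time.perf_counter() - t0)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def configure_logging(verbose: bool = True) -> None:
    """Stage-timer logging to stderr (reports themselves stay plain files)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
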