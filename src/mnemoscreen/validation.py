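"""Internal validation of a screening rule: bootstrap and stratified analysis.

Bootstrap internal validation resamples visits with replacement, recomputes
the rule's seven-statistic profile on each resample's evaluable subset, and
reports per-statistic bootstrap mean/median, percentile CI and bias — the
standard check that a rule selected on a cohort is stable within it.

Stratified analysis recomputes the rule profile per level of a covariate
(sex, age group, smoking, obesity, diabetes, hypertension) and compares two
strata both ways the field uses: overlap of the 95% CIs, and a Wald z-test
on the difference of transformed estimates (log for ratios, logit for
proportions) with independent-stratum standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOME_POSITIVE, CohortTable
from .metrics import (
    STATISTICS,
    DiagnosticProfile,
    TwoByTwo,
    cross_tabulate,
    diagnostic_profile,
    transformed_estimate,
)
from .rules import CompositeRule

__all__ = [
    "BootstrapStat",
    "BootstrapReport",
    "StratumResult",
    "StratumComparison",
    "bootstrap_validate",
    "stratified_profiles",
    "compare_strata",
]


@dataclass(frozen=True)
class BootstrapStat:
    original: float
    boot_mean: float
    boot_median: float
    ci_lower: float
    ci_upper: float

    @property
    def bias(self) -> float:
        return self.boot_mean - self.original


@dataclass(frozen=True)
class BootstrapReport:
    B: int
    seed: int | None
    n_redrawn: int
    statistics: Mapping[str, BootstrapStat]

    def statistic(self, name: str) -> BootstrapStat:
        return self.statistics[name]


@dataclass(frozen=True)
class StratumResult:
    """Per-level rule profile; ``profile`` is None when not estimable."""

    level: str
    n_rows: int
    table: TwoByTwo | None
    profile: DiagnosticProfile | None
    reason: str = ""


@dataclass(frozen=True)
class StratumComparison:
    statistic: str
    level_a: str
    level_b: str
    difference: float  # on the transformed scale (log or logit), a - b
    se: float
    z: float
    p: float
    ci_overlap: bool


def _stat_points(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized seven-statistic point estimates for stacked (a,b,c,d) rows.

    Rows containing a zero cell get the Haldane-Anscombe +0.5 on all four
    cells for the three ratio statistics (proportions are left exact).
    """
    a, b, c, d = (counts[:, i].astype(float) for i in range(4))
    zero = (counts == 0).any(axis=1)
    fa, fb, fc, fd = (x + np.where(zero, 0.5, 0.0) for x in (a, b, c, d))
    with np.errstate(divide="ignore", invalid="ignore"):
        return {
            "sensitivity": a / (a + c),
            "specificity": d / (b + d),
            "ppv": np.where(a + b > 0, a / np.maximum(a + b, 1), np.nan),
            "npv": np.where(c + d > 0, d / np.maximum(c + d, 1), np.nan),
            "lr_pos": (fa / (fa + fc)) / (fb / (fb + fd)),
            "lr_neg": (fc / (fa + fc)) / (fd / (fb + fd)),
            "odds_ratio": (fa * fd) / (fb * fc),
        }


def bootstrap_validate(
    cohort: CohortTable,
    rule: CompositeRule,
    B: int = 1000,
    seed: int | None = None,
    outcome_stratified: bool = False,
    alpha: float = 0.05,
) -> BootstrapReport:
    """Bootstrap the rule's diagnostic profile over ``B`` row resamples.

    Resample size equals the cohort size; the rule profile is recomputed on
    each resample's evaluable subset.  A resample with an empty outcome
    margin (no ACS or no non-ACS among evaluable rows) is redrawn and
    counted.  ``outcome_stratified`` resamples within outcome class instead,
    preserving the case/non-case split.  Deterministic under a fixed seed.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    states = rule.evaluate(cohort)
    disease = (cohort.df["outcome"] == OUTCOME_POSITIVE).to_numpy()
    rec = states.notna().to_numpy()
    pos = states.fillna(False).to_numpy(dtype=bool)
    # per-row cell code: 0=a, 1=b, 2=c, 3=d, 4=not evaluable
    codes = np.full(len(cohort.df), 4, dtype=np.int64)
    codes[rec & pos & disease] = 0
    codes[rec & pos & ~disease] = 1
    codes[rec & ~pos & disease] = 2
    codes[rec & ~pos & ~disease] = 3

    original = cross_tabulate(cohort, rule)
    orig_prof = diagnostic_profile(original, alpha=alpha)

    rng = np.random.default_rng(seed)
    n = len(codes)
    pos_idx = np.where(disease)[0]
    neg_idx = np.where(~disease)[0]

    tables = np.empty((B, 4), dtype=np.int64)
    n_redrawn = 0
    filled = 0
    while filled < B:
        if outcome_stratified:
            idx = np.concatenate([
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ])
        else:
            idx = rng.integers(0, n, n)
        cnt = np.bincount(codes[idx], minlength=5)[:4]
        if cnt[0] + cnt[2] == 0 or cnt[1] + cnt[3] == 0:
            n_redrawn += 1
            if n_redrawn > 100 * B:
                raise RuntimeError(
                    "bootstrap cannot produce a resample with both outcome "
                    "classes evaluable; consider outcome_stratified=True"
                )
            continue
        tables[filled] = cnt
        filled += 1

    points = _stat_points(tables)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out: dict[str, BootstrapStat] = {}
    for stat in STATISTICS:
        vals = points[stat]
        out[stat] = BootstrapStat(
            original=orig_prof.statistic(stat).point,
            boot_mean=float(np.nanmean(vals)),
            boot_median=float(np.nanmedian(vals)),
            ci_lower=float(np.nanpercentile(vals, lo_q)),
            ci_upper=float(np.nanpercentile(vals, hi_q)),
        )
    return BootstrapReport(B=B, seed=seed, n_redrawn=n_redrawn, statistics=out)


def stratified_profiles(
    cohort: CohortTable,
    rule: CompositeRule,
    stratum: str,
    alpha: float = 0.05,
) -> dict[str, StratumResult]:
    """Complete-case rule profile per level of a covariate.

    Levels whose 2x2 table has an empty margin are reported as not
    estimable rather than dropped.  Rows with the covariate unrecorded
    belong to no level.
    """
    if stratum not in cohort.df.columns:
        raise KeyError(f"unknown covariate {stratum!r}")
    col = cohort.df[stratum]
    levels = sorted(col.dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"stratum {stratum!r} has fewer than two levels")
    results: dict[str, StratumResult] = {}
    for level in levels:
        sub_df = cohort.df.loc[col == level]
        if len(sub_df) == 0:
            results[level] = StratumResult(level, 0, None, None, "no rows")
            continue
        sub = CohortTable(sub_df.copy(), cohort.symptom_names, cohort.provenance)
        try:
            table = cross_tabulate(sub, rule)
        except ValueError:
            results[level] = StratumResult(level, len(sub_df), None, None,
                                           "no evaluable rows")
            continue
        if table.n_outcome_pos == 0 or table.n_outcome_neg == 0:
            results[level] = StratumResult(level, len(sub_df), table, None,
                                           "empty outcome margin")
            continue
        results[level] = StratumResult(
            level, len(sub_df), table, diagnostic_profile(table, alpha=alpha)
        )
    return results


def compare_strata(
    pa: DiagnosticProfile,
    pb: DiagnosticProfile,
    statistic: str,
    level_a: str = "a",
    level_b: str = "b",
) -> StratumComparison:
    """Two-stratum comparison of one statistic.

    Reports both a Wald z-test on the difference of transformed estimates
    (independent-stratum SEs) and whether the two 95% CIs overlap — the
    criterion behind "no statistically significant difference between
    subgroups" statements.  Symmetric up to the sign of the difference.
    """
    if statistic not in STATISTICS:
        raise KeyError(f"unknown statistic {statistic!r}")
    qa, va, _ = transformed_estimate(pa.table, statistic)
    qb, vb, _ = transformed_estimate(pb.table, statistic)
    diff = qa - qb
    se = math.sqrt(va + vb)
    z = diff / se if se > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
    ea, eb = pa.statistic(statistic), pb.statistic(statistic)
    overlap = (ea.lower <= eb.upper) and (eb.lower <= ea.upper)
    return StratumComparison(
        statistic=statistic, level_a=level_a, level_b=level_b,
        difference=diff, se=se, z=z, p=p, ci_overlap=overlap,
    )
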