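"""Synthetic ER cohorts with the statistical structure the analysis assumes.

The reference study conditions are a Thai tertiary-care ER cohort of 3,400
visits (2020-2021) with suspected-ACS symptoms and an ACS prevalence of
12.2% (415/3,400).  Each symptom was recorded for only a subset of visits
(charts rarely mention every symptom), so every per-symptom analysis has its
own denominator.  This module provides:

* :data:`REFERENCE_SYMPTOM_TABLES` — the per-symptom 2x2 counts of that
  cohort (predictor x outcome, complete-case);
* :func:`default_cohort_params` — generative parameters whose class-
  conditional symptom frequencies, recording rates and covariate mix match
  those margins;
* :func:`generate` — a reproducible cohort simulator (independent symptoms
  by default, optional Gaussian copula for joint structure, MCAR or
  outcome-dependent MAR recording);
* :func:`make_reference_cohort` — a deterministic 3,400-row table whose
  per-symptom cross-tabulations equal the reference counts *exactly*.

Only the per-symptom margins of the reference cohort are public; the joint
symptom co-occurrence structure is not, so composite-rule performance on
synthetic cohorts is a modeling device, not a reproduction of the study's
composite numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOME_NEGATIVE, OUTCOME_POSITIVE, SYMPTOMS, CohortTable

__all__ = [
    "REFERENCE_N",
    "REFERENCE_N_ACS",
    "REFERENCE_SYMPTOM_TABLES",
    "CohortParams",
    "default_cohort_params",
    "generate",
    "make_reference_cohort",
]

REFERENCE_N = 3400
REFERENCE_N_ACS = 415

#: Per-symptom complete-case 2x2 counts (a, b, c, d) of the reference cohort:
#: a = present & ACS, b = present & non-ACS, c = absent & ACS, d = absent & non-ACS.
#: a+b+c+d is that symptom's recorded-visit count.
REFERENCE_SYMPTOM_TABLES: dict[str, tuple[int, int, int, int]] = {
    "chest_pain":       (367, 1539, 34, 1055),   # n=2995
    "referred_pain":    (139, 333, 160, 1233),   # n=1865
    "sweating":         (132, 320, 180, 1337),   # n=1969
    "dyspnea":          (140, 769, 146, 1127),   # n=2182
    "palpitation":      (116, 663, 204, 1552),   # n=2535
    "nausea":           (28, 396, 69, 863),      # n=1356
    "dizziness":        (19, 371, 6, 101),       # n=497
    "presyncope":       (32, 347, 109, 708),     # n=1196
    "epigastrium_pain": (39, 725, 11, 100),      # n=875
    "syncope":          (3, 68, 66, 533),        # n=670
}

#: Class-conditional covariate distributions of the reference cohort.
#: Each entry: levels, P(level | ACS), P(level | non-ACS), and the
#: class-conditional probability the covariate was recorded at all.
_REFERENCE_COVARIATES: dict[str, dict] = {
    "sex": {
        "levels": ("male", "female"),
        "p_pos": (311 / 415, 104 / 415),
        "p_neg": (1423 / 2985, 1562 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "age_group": {
        "levels": (">=60", "<60"),
        "p_pos": (296 / 415, 119 / 415),
        "p_neg": (1773 / 2985, 1212 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "bmi_group": {
        "levels": ("obese", "overweight", "normal", "underweight"),
        "p_pos": (153 / 370, 94 / 370, 107 / 370, 16 / 370),
        "p_neg": (977 / 2398, 509 / 2398, 749 / 2398, 163 / 2398),
        "record_pos": 370 / 415, "record_neg": 2398 / 2985,
    },
    "smoking": {
        "levels": ("current", "ex", "never"),
        "p_pos": (65 / 285, 36 / 285, 184 / 285),
        "p_neg": (145 / 1773, 179 / 1773, 1449 / 1773),
        "record_pos": 285 / 415, "record_neg": 1773 / 2985,
    },
    "hypertension": {
        "levels": ("1", "0"),
        "p_pos": (228 / 415, 187 / 415),
        "p_neg": (1274 / 2985, 1711 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "dyslipidemia": {
        "levels": ("1", "0"),
        "p_pos": (173 / 415, 242 / 415),
        "p_neg": (1025 / 2985, 1960 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "CAD": {
        "levels": ("1", "0"),
        "p_pos": (190 / 415, 225 / 415),
        "p_neg": (648 / 2985, 2337 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "DM": {
        "levels": ("1", "0"),
        "p_pos": (147 / 415, 268 / 415),
        "p_neg": (652 / 2985, 2333 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "CVA": {
        "levels": ("1", "0"),
        "p_pos": (32 / 415, 383 / 415),
        "p_neg": (227 / 2985, 2758 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
    "PAD": {
        "levels": ("1", "0"),
        "p_pos": (9 / 415, 406 / 415),
        "p_neg": (23 / 2985, 2962 / 2985),
        "record_pos": 1.0, "record_neg": 1.0,
    },
}


@dataclass
class CohortParams:
    """Generative parameters for a synthetic suspected-ACS cohort.

    ``p_pos[s]`` / ``p_neg[s]`` are P(symptom present | ACS) / P(present |
    non-ACS); ``record_rate[s]`` is the probability the chart records the
    symptom at all.  ``copula_correlation`` (optional, symptoms x symptoms,
    unit diagonal, PSD) induces joint symptom dependence through a Gaussian
    copula; the default ``None`` means conditional independence.  Recording
    is MCAR by default; ``MAR_on_outcome`` inflates the recording odds for
    ACS visits by ``mar_multiplier`` while preserving the marginal rate.
    """

    n: int
    prevalence: float
    p_pos: dict[str, float]
    p_neg: dict[str, float]
    record_rate: dict[str, float]
    mechanism: Literal["MCAR", "MAR_on_outcome"] = "MCAR"
    mar_multiplier: float = 1.5
    copula_correlation: np.ndarray | None = None
    covariate_params: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0,1]")
        for name, mapping in (("p_pos", self.p_pos), ("p_neg", self.p_neg),
                              ("record_rate", self.record_rate)):
            for s, p in mapping.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{s!r}]={p} outside [0,1]")
        if set(self.p_pos) != set(self.p_neg) or set(self.p_pos) != set(self.record_rate):
            raise ValueError("p_pos, p_neg and record_rate must share symptom names")
        if self.copula_correlation is not None:
            r = np.asarray(self.copula_correlation, dtype=float)
            k = len(self.symptom_names)
            if r.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k}")
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-8:
                raise ValueError("correlation matrix is not positive semi-definite")
            self.copula_correlation = r

    @property
    def symptom_names(self) -> tuple[str, ...]:
        return tuple(self.p_pos)


def default_cohort_params(seed: int | None = None) -> CohortParams:
    """Parameters matching the reference cohort's margins.

    Prevalence 415/3,400; for each symptom, class-conditional presence
    probabilities among recorded visits (e.g. chest pain 367/401 given ACS,
    1,539/2,594 given non-ACS) and the recording rate n_s/3,400 (e.g.
    dizziness 497/3,400).  MCAR recording, independent symptoms.
    """
    p_pos, p_neg, rec = {}, {}, {}
    for s, (a, b, c, d) in REFERENCE_SYMPTOM_TABLES.items():
        p_pos[s] = a / (a + c)
        p_neg[s] = b / (b + d)
        rec[s] = (a + b + c + d) / REFERENCE_N
    return CohortParams(
        n=REFERENCE_N,
        prevalence=REFERENCE_N_ACS / REFERENCE_N,
        p_pos=p_pos,
        p_neg=p_neg,
        record_rate=rec,
        covariate_params={k: dict(v) for k, v in _REFERENCE_COVARIATES.items()},
        seed=seed,
    )


def _mar_rates(rate: float, prevalence: float, mult: float) -> tuple[float, float]:
    """Class-conditional recording rates whose mixture equals ``rate``."""
    r_pos = min(1.0, rate * mult)
    if prevalence >= 1.0:
        return r_pos, 0.0
    r_neg = (rate - prevalence * r_pos) / (1.0 - prevalence)
    return r_pos, float(np.clip(r_neg, 0.0, 1.0))


def generate(params: CohortParams, seed: int | None = None) -> CohortTable:
    """Simulate a cohort from ``params``; fully reproducible under a seed.

    Outcome ~ Bernoulli(prevalence); symptom presence from the class-
    conditional margins (via Gaussian-copula thresholds when a correlation
    is set); the recording mask is applied *after* presence is drawn, from
    an independent random stream, so unmasking (record_rate = 1, same seed)
    reveals the same underlying presence states.
    """
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    rng_outcome, rng_presence, rng_mask, rng_cov = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    n = params.n
    symptoms = params.symptom_names
    acs = rng_outcome.random(n) < params.prevalence

    p_mat = np.where(
        acs[:, None],
        np.array([params.p_pos[s] for s in symptoms])[None, :],
        np.array([params.p_neg[s] for s in symptoms])[None, :],
    )
    if params.copula_correlation is None:
        present = rng_presence.random((n, len(symptoms))) < p_mat
    else:
        z = rng_presence.multivariate_normal(
            np.zeros(len(symptoms)), params.copula_correlation, size=n,
            method="eigh",
        )
        present = z < stats.norm.ppf(np.clip(p_mat, 1e-12, 1 - 1e-12))

    u_mask = rng_mask.random((n, len(symptoms)))
    df = pd.DataFrame({
        "visit_id": [f"V{i + 1:06d}" for i in range(n)],
        "outcome": np.where(acs, OUTCOME_POSITIVE, OUTCOME_NEGATIVE),
    })
    for j, s in enumerate(symptoms):
        rate = params.record_rate[s]
        if params.mechanism == "MCAR":
            recorded = u_mask[:, j] < rate
        elif params.mechanism == "MAR_on_outcome":
            r_pos, r_neg = _mar_rates(rate, params.prevalence, params.mar_multiplier)
            recorded = u_mask[:, j] < np.where(acs, r_pos, r_neg)
        else:
            raise ValueError(f"unknown mechanism {params.mechanism!r}")
        col = pd.array(present[:, j], dtype="boolean")
        col[~recorded] = pd.NA
        df[s] = col

    for name, spec in params.covariate_params.items():
        levels = list(spec["levels"])
        pp = np.asarray(spec["p_pos"], dtype=float)
        pn = np.asarray(spec["p_neg"], dtype=float)
        pp, pn = pp / pp.sum(), pn / pn.sum()
        draws_pos = rng_cov.choice(len(levels), size=n, p=pp)
        draws_neg = rng_cov.choice(len(levels), size=n, p=pn)
        idx = np.where(acs, draws_pos, draws_neg)
        vals = pd.Series([levels[i] for i in idx], index=df.index, dtype="object")
        rec_p = np.where(acs, spec.get("record_pos", 1.0), spec.get("record_neg", 1.0))
        vals[rng_cov.random(n) >= rec_p] = pd.NA
        df[name] = vals

    return CohortTable(df, symptom_names=symptoms, provenance="synthetic")


def _quota_fill(k: int, quotas: list[tuple[object, int]]) -> list:
    """Deterministically assign ``k`` slots from ordered (value, count) quotas;
    remaining slots get pd.NA."""
    out: list = []
    for value, count in quotas:
        out.extend([value] * count)
    if len(out) > k:
        raise ValueError("quotas exceed available rows")
    out.extend([pd.NA] * (k - len(out)))
    return out


def make_reference_cohort() -> CohortTable:
    """Deterministic 3,400-row cohort whose per-symptom cross-tabulations
    equal the reference counts exactly.

    Each symptom's recorded/present quota is filled independently row-by-row
    within outcome class, so only the marginal 2x2 tables are faithful; the
    joint structure across symptoms is an artifact of the fill order and is
    asserted nowhere.  Covariate margins are filled the same way.  Intended
    as a test fixture and for exact reproduction of per-symptom performance.
    """
    n_pos, n_neg = REFERENCE_N_ACS, REFERENCE_N - REFERENCE_N_ACS
    df = pd.DataFrame({
        "visit_id": [f"R{i + 1:06d}" for i in range(REFERENCE_N)],
        "outcome": [OUTCOME_POSITIVE] * n_pos + [OUTCOME_NEGATIVE] * n_neg,
    })
    for s, (a, b, c, d) in REFERENCE_SYMPTOM_TABLES.items():
        col = (_quota_fill(n_pos, [(True, a), (False, c)])
               + _quota_fill(n_neg, [(True, b), (False, d)]))
        df[s] = pd.array(col, dtype="boolean")
    for name, spec in _REFERENCE_COVARIATES.items():
        rec_pos = round(spec["record_pos"] * n_pos)
        rec_neg = round(spec["record_neg"] * n_neg)
        quota_pos = [(lvl, round(p * rec_pos)) for lvl, p in
                     zip(spec["levels"], spec["p_pos"])]
        quota_neg = [(lvl, round(p * rec_neg)) for lvl, p in
                     zip(spec["levels"], spec["p_neg"])]
        # rounding drift goes to the last (largest-remainder not needed at
        # this scale): trim or pad the final level to hit the recorded count
        for quotas, rec in ((quota_pos, rec_pos), (quota_neg, rec_neg)):
            drift = rec - sum(cnt for _, cnt in quotas)
            lvl, cnt = quotas[-1]
            quotas[-1] = (lvl, cnt + drift)
        df[name] = pd.Series(
            _quota_fill(n_pos, quota_pos) + _quota_fill(n_neg, quota_neg),
            dtype="object",
        )
    cohort = CohortTable(df, provenance="reference-margins fixture")

    # self-check: every symptom's 2x2 must match the reference exactly
    from .metrics import cross_tabulate

    for s, (a, b, c, d) in REFERENCE_SYMPTOM_TABLES.items():
        t = cross_tabulate(cohort, s)
        if (t.a, t.b, t.c, t.d) != (a, b, c, d):
            raise AssertionError(f"fixture margin mismatch for {s}: {t}")
    return cohort
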