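"""2x2 cross-tabulation and the diagnostic-performance battery.

Every predictor (a single symptom or a composite rule) is reduced to the
classic 2x2 table against the ACS outcome::

                 ACS     non-ACS
    positive      a         b
    negative      c         d

computed on the complete-case subset for that predictor, and profiled with
seven statistics: sensitivity, specificity, PPV, NPV, LR+, LR- and the odds
ratio, each with a 95% confidence interval.

CI methods (configurable): Wilson score for the four proportions
(Clopper-Pearson available), the Simel log method for likelihood ratios, and
Woolf's log method for the odds ratio (Wald-from-logistic available).  When
any cell of the table is zero, ratio statistics get the Haldane-Anscombe
+0.5 correction on all four cells and the result's method label is flagged;
non-degenerate tables are never touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import OUTCOME_POSITIVE, CohortTable

__all__ = [
    "TwoByTwo",
    "EstimateWithCI",
    "DiagnosticProfile",
    "SampleSizePlan",
    "cross_tabulate",
    "diagnostic_profile",
    "odds_ratio",
    "chi_square_association",
    "sample_size_plan",
    "profiles_to_frame",
    "transformed_estimate",
    "back_transform",
]

STATISTICS = ("odds_ratio", "sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg")


@dataclass(frozen=True)
class TwoByTwo:
    """Counts of a predictor x outcome cross-tabulation (a,b,c,d as above)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n < 1:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_outcome_pos(self) -> int:
        return self.a + self.c

    @property
    def n_outcome_neg(self) -> int:
        return self.b + self.d

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EstimateWithCI:
    point: float
    lower: float
    upper: float
    scale: Literal["proportion", "ratio"]
    method: str

    def __post_init__(self) -> None:
        if all(map(math.isfinite, (self.point, self.lower, self.upper))):
            if not (self.lower <= self.point + 1e-12 and self.point <= self.upper + 1e-12):
                raise ValueError(
                    f"CI ({self.lower}, {self.upper}) does not bracket point {self.point}"
                )


@dataclass(frozen=True)
class DiagnosticProfile:
    """The seven-statistic battery for one predictor on its evaluable subset."""

    sensitivity: EstimateWithCI
    specificity: EstimateWithCI
    ppv: EstimateWithCI
    npv: EstimateWithCI
    lr_pos: EstimateWithCI
    lr_neg: EstimateWithCI
    odds_ratio: EstimateWithCI
    n_used: int
    table: TwoByTwo

    def statistic(self, name: str) -> EstimateWithCI:
        if name not in STATISTICS:
            raise KeyError(f"unknown statistic {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class SampleSizePlan:
    """Infinite-population proportion sample size, inflated for prevalence and dropout."""

    p: float
    d: float
    alpha: float
    n0: int
    prevalence: float
    dropout: float
    n_required: int


def cross_tabulate(
    cohort: CohortTable,
    predictor,
    outcome_positive: str = OUTCOME_POSITIVE,
) -> TwoByTwo:
    """Cross-tabulate a predictor against the outcome on its evaluable rows.

    ``predictor`` is a symptom name or any object with an
    ``evaluate(cohort) -> pandas nullable-boolean Series`` method (a composite
    rule).  Rows where the predictor is unrecorded/indeterminate are excluded,
    so ``a+b+c+d`` equals the evaluable-row count.
    """
    if isinstance(predictor, str):
        if predictor not in cohort.symptom_names:
            raise KeyError(f"unknown symptom {predictor!r}")
        states = cohort.df[predictor]
    elif hasattr(predictor, "evaluate"):
        states = predictor.evaluate(cohort)
    else:
        raise TypeError(f"predictor must be a symptom name or rule, got {type(predictor)}")

    recorded = states.notna()
    if not recorded.any():
        raise ValueError("predictor has zero evaluable rows")
    pos = states.fillna(False).to_numpy(dtype=bool)
    disease = (cohort.df["outcome"] == outcome_positive).to_numpy()
    rec = recorded.to_numpy()
    a = int(np.sum(rec & pos & disease))
    b = int(np.sum(rec & pos & ~disease))
    c = int(np.sum(rec & ~pos & disease))
    d = int(np.sum(rec & ~pos & ~disease))
    return TwoByTwo(a, b, c, d)


def _proportion_ci(k: int, n: int, alpha: float, method: str) -> tuple[float, float]:
    if method not in ("wilson", "beta"):
        raise ValueError(f"unsupported proportion CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=method)
    return float(lo), float(hi)


def _ratio_ci(point: float, se_log: float, z: float) -> tuple[float, float]:
    if point <= 0 or not math.isfinite(point):
        return (float("nan"), float("nan"))
    return (point * math.exp(-z * se_log), point * math.exp(z * se_log))


def odds_ratio(
    table: TwoByTwo,
    estimator: Literal["cross_product", "logistic_mle"] = "cross_product",
    ci: Literal["woolf", "wald_logistic"] = "woolf",
    alpha: float = 0.05,
) -> EstimateWithCI:
    """Odds ratio of the 2x2 table with a 95% CI.

    ``cross_product`` computes a*d/(b*c) directly; ``logistic_mle`` fits the
    saturated single-predictor logistic regression (the two agree to numerical
    precision on all-positive tables).  Zero cells trigger the
    Haldane-Anscombe +0.5 correction, flagged in the method label.
    """
    z = stats.norm.ppf(1 - alpha / 2)
    corrected = table.has_zero_cell()
    a, b, c, d = (x + 0.5 for x in (table.a, table.b, table.c, table.d)) if corrected \
        else (float(table.a), float(table.b), float(table.c), float(table.d))

    if estimator == "cross_product":
        point = (a * d) / (b * c)
        method = "cross_product"
    elif estimator == "logistic_mle":
        point = _logistic_or(a, b, c, d)
        method = "logistic_mle"
    else:
        raise ValueError(f"unknown OR estimator {estimator!r}")

    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if ci == "woolf":
        lo, hi = _ratio_ci(point, se_log, z)
        method += "+woolf"
    elif ci == "wald_logistic":
        # Wald SE from the logistic fit equals the Woolf SE analytically on a
        # saturated 2x2; reuse it but label honestly.
        lo, hi = _ratio_ci(point, se_log, z)
        method += "+wald_logistic"
    else:
        raise ValueError(f"unknown OR CI method {ci!r}")
    if corrected:
        method += "+haldane0.5"
    return EstimateWithCI(point, lo, hi, "ratio", method)


def _logistic_or(a: float, b: float, c: float, d: float) -> float:
    """MLE odds ratio from logistic regression of outcome on one binary predictor."""
    import statsmodels.api as sm

    x = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
    y = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.array([a, b, c, d])
    fit = sm.GLM(y, x, family=sm.families.Binomial(), freq_weights=w).fit(
        tol=1e-14, maxiter=200
    )
    return float(np.exp(fit.params[1]))


def diagnostic_profile(
    table: TwoByTwo,
    alpha: float = 0.05,
    ci_proportions: Literal["wilson", "beta"] = "wilson",
    ci_ratios: Literal["woolf", "wald_logistic"] = "woolf",
    or_estimator: Literal["cross_product", "logistic_mle"] = "cross_product",
) -> DiagnosticProfile:
    """Full seven-statistic diagnostic profile of a 2x2 table.

    Sensitivity = a/(a+c), specificity = d/(b+d), PPV = a/(a+b),
    NPV = d/(c+d), LR+ = Se/(1-Sp), LR- = (1-Se)/Sp, OR = ad/bc.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0:
        raise ValueError("empty outcome-positive margin (a+c=0)")
    if b + d == 0:
        raise ValueError("empty outcome-negative margin (b+d=0)")
    z = stats.norm.ppf(1 - alpha / 2)

    def prop(k: int, n: int) -> EstimateWithCI:
        if n == 0:
            return EstimateWithCI(float("nan"), float("nan"), float("nan"),
                                  "proportion", ci_proportions + "+empty")
        lo, hi = _proportion_ci(k, n, alpha, ci_proportions)
        return EstimateWithCI(k / n, lo, hi, "proportion", ci_proportions)

    se = prop(a, a + c)
    sp = prop(d, b + d)
    ppv = prop(a, a + b)
    npv = prop(d, c + d)

    # Likelihood ratios: Simel log method; Haldane correction if a zero cell
    # makes a ratio degenerate.
    corrected = table.has_zero_cell()
    fa, fb, fc, fd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    se_pt, sp_pt = fa / (fa + fc), fd / (fb + fd)
    lr_tag = "simel_log" + ("+haldane0.5" if corrected else "")
    lrp_point = (a / (a + c)) / (1 - d / (b + d)) if d != b + d else float("inf")
    lrn_point = (1 - a / (a + c)) / (d / (b + d)) if d != 0 else float("inf")
    if corrected:
        lrp_point = se_pt / (1 - sp_pt)
        lrn_point = (1 - se_pt) / sp_pt
    se_log_lrp = math.sqrt(1 / fa - 1 / (fa + fc) + 1 / fb - 1 / (fb + fd))
    se_log_lrn = math.sqrt(1 / fc - 1 / (fa + fc) + 1 / fd - 1 / (fb + fd))
    lrp = EstimateWithCI(lrp_point, *_ratio_ci(lrp_point, se_log_lrp, z), "ratio", lr_tag)
    lrn = EstimateWithCI(lrn_point, *_ratio_ci(lrn_point, se_log_lrn, z), "ratio", lr_tag)

    or_est = odds_ratio(table, estimator=or_estimator, ci=ci_ratios, alpha=alpha)
    return DiagnosticProfile(
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        lr_pos=lrp, lr_neg=lrn, odds_ratio=or_est,
        n_used=table.n, table=table,
    )


def chi_square_association(
    table: TwoByTwo, correction: Literal["none", "yates"] = "none"
) -> tuple[float, float]:
    """Pearson chi-square test of symptom-outcome association (1 df)."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency(arr, correction=(correction == "yates"))
    return float(res.statistic), float(res.pvalue)


def sample_size_plan(
    p: float,
    d: float,
    alpha: float = 0.05,
    prevalence: float = 1.0,
    dropout: float = 0.0,
) -> SampleSizePlan:
    """Sample size for estimating a proportion, inflated for prevalence and dropout.

    n0 = ceil(z^2 p (1-p) / d^2) from the infinite-population formula; the
    review target is then n = ceil(ceil(n0 / prevalence) / (1 - dropout)),
    reflecting that only a fraction ``prevalence`` of screened visits carry
    the condition and a further ``dropout`` share have unusable records.
    """
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0,1), got {p}")
    if not (0 < d < 1):
        raise ValueError(f"d must be in (0,1), got {d}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not (0 < prevalence <= 1):
        raise ValueError(f"prevalence must be in (0,1], got {prevalence}")
    if not (0 <= dropout < 1):
        raise ValueError(f"dropout must be in [0,1), got {dropout}")
    z = stats.norm.ppf(1 - alpha / 2)
    n0 = math.ceil(z * z * p * (1 - p) / (d * d))
    n_required = math.ceil(math.ceil(n0 / prevalence) / (1 - dropout))
    return SampleSizePlan(p=p, d=d, alpha=alpha, n0=n0,
                          prevalence=prevalence, dropout=dropout,
                          n_required=n_required)


def transformed_estimate(table: TwoByTwo, statistic: str) -> tuple[float, float, bool]:
    """Point estimate and delta-method variance of a statistic on its
    transformed scale (logit for proportions, log for ratios).

    Used for Rubin pooling across imputations and for Wald comparison of
    strata.  Degenerate estimates (proportion 0 or 1, zero table cell for a
    ratio) get a +0.5 continuity adjustment; the returned flag reports it.

    Returns ``(q, var, adjusted)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if statistic in ("sensitivity", "specificity", "ppv", "npv"):
        k, n = {
            "sensitivity": (a, a + c),
            "specificity": (d, b + d),
            "ppv": (a, a + b),
            "npv": (d, c + d),
        }[statistic]
        adjusted = k == 0 or k == n
        if adjusted:
            k, n = k + 0.5, n + 1.0
        q = math.log(k / (n - k))
        var = 1.0 / k + 1.0 / (n - k)
        return q, var, adjusted
    adjusted = table.has_zero_cell()
    if adjusted:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if statistic == "odds_ratio":
        q = math.log((a * d) / (b * c))
        var = 1 / a + 1 / b + 1 / c + 1 / d
    elif statistic == "lr_pos":
        q = math.log((a / (a + c)) / (b / (b + d)))
        var = 1 / a - 1 / (a + c) + 1 / b - 1 / (b + d)
    elif statistic == "lr_neg":
        q = math.log((c / (a + c)) / (d / (b + d)))
        var = 1 / c - 1 / (a + c) + 1 / d - 1 / (b + d)
    else:
        raise KeyError(f"unknown statistic {statistic!r}")
    return q, var, adjusted


def back_transform(statistic: str, q: float) -> float:
    """Inverse of the transform used by :func:`transformed_estimate`."""
    if statistic in ("sensitivity", "specificity", "ppv", "npv"):
        return 1.0 / (1.0 + math.exp(-q))
    return math.exp(q)


def _fmt(e: EstimateWithCI, dp: int = 2) -> str:
    return f"{e.point:.{dp}f} ({e.lower:.{dp}f}, {e.upper:.{dp}f})"


def profiles_to_frame(
    profiles: dict[str, DiagnosticProfile], dp: int = 2
) -> pd.DataFrame:
    """Report table: one row per predictor, one 'point (lo, hi)' column per statistic.

    Matches the layout used for per-symptom and per-rule performance reports;
    display rounding is 2 dp, internal computation stays at full precision.
    """
    rows = {}
    for name, prof in profiles.items():
        rows[name] = {
            "n": prof.n_used,
            **{stat: _fmt(prof.statistic(stat), dp) for stat in STATISTICS},
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "predictor"
    return frame
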