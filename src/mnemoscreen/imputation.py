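"""Multiple imputation of unrecorded symptom states and Rubin pooling.

Charts that never mention a symptom leave a hole that complete-case analysis
discards.  This module fills those holes with *m* stochastic completions and
pools the per-completion diagnostic profiles with Rubin's rules.

The default imputer is a bootstrap-EM latent-normal model: for each of the
m completions, the rows are resampled with replacement, the mean vector and
covariance of a multivariate-normal working model over the binary indicators
(symptoms + outcome + fully observed binary covariates) are estimated by EM
on the resample, and each missing cell of the *original* data is then given
its conditional mean under that model; the conditional mean, truncated to
[0, 1], is the predicted probability from which the imputed binary state is
drawn Bernoulli.  Resampling before EM propagates parameter uncertainty
into the imputations (proper MI); the Bernoulli draw supplies the binary
residual variance.  A chained-logistic fallback is available.

The outcome is a predictor in the imputation model and is itself never
imputed, so class-conditional symptom structure survives completion.
Recorded cells are never altered.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import OUTCOME_POSITIVE, CohortTable
from .metrics import (
    STATISTICS,
    DiagnosticProfile,
    EstimateWithCI,
    back_transform,
    cross_tabulate,
    diagnostic_profile,
    transformed_estimate,
)

__all__ = [
    "ImputationConfig",
    "PooledProfile",
    "impute",
    "pool_profiles",
    "pooled_profile_for",
    "stacked_profile",
]

#: Covariates with a natural binary encoding usable in the imputation model.
_BINARY_COVARIATE_CODES = {
    "sex": {"male": 1.0, "female": 0.0},
    "age_group": {">=60": 1.0, "<60": 0.0},
    "hypertension": {"1": 1.0, "0": 0.0},
    "dyslipidemia": {"1": 1.0, "0": 0.0},
    "CAD": {"1": 1.0, "0": 0.0},
    "DM": {"1": 1.0, "0": 0.0},
    "CVA": {"1": 1.0, "0": 0.0},
    "PAD": {"1": 1.0, "0": 0.0},
}


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for multiple imputation.

    ``variables``: covariate columns to include as predictors alongside the
    symptoms and the outcome (default: every fully observed binary covariate
    present in the cohort).  ``m`` completed datasets are produced from
    ``seed``; identical (cohort, config) gives identical output.
    """

    m: int = 5
    seed: int | None = None
    method: Literal["em_bootstrap_latent_normal", "logistic_cc"] = (
        "em_bootstrap_latent_normal"
    )
    variables: tuple[str, ...] | None = None
    em_max_iter: int = 60
    em_tol: float = 1e-5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")


@dataclass(frozen=True)
class PooledProfile:
    """Rubin-pooled diagnostic profile across m completed datasets.

    Pooling is on the log scale for OR/LR and the logit scale for the four
    proportions; total variance = within + (1 + 1/m) * between, CI df by
    Barnard-Rubin.
    """

    estimates: dict[str, EstimateWithCI]
    within_var: dict[str, float]
    between_var: dict[str, float]
    total_var: dict[str, float]
    m: int
    n_used: int

    def statistic(self, name: str) -> EstimateWithCI:
        return self.estimates[name]

    # convenience mirrors of DiagnosticProfile's attributes
    def __getattr__(self, name: str):
        est = self.__dict__.get("estimates", {})
        if name in est:
            return est[name]
        raise AttributeError(name)


# ---------------------------------------------------------------------------
# EM for a multivariate normal with missing data
# ---------------------------------------------------------------------------

def _em_mvn(
    X: np.ndarray, max_iter: int, tol: float, ridge: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """EM estimate of (mu, Sigma) of an MVN from data with missing entries."""
    n, p = X.shape
    miss = np.isnan(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(X, axis=0)
        var = np.nanvar(X, axis=0)
    mu = np.where(np.isnan(mu), 0.5, mu)
    var = np.where(np.isnan(var) | (var < 1e-4), 0.25, var)
    sigma = np.diag(var)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(miss, axis=0):
        rows = np.where((miss == key).all(axis=1))[0]
        patterns[key.tobytes()] = (key, rows)  # type: ignore[assignment]

    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for key, rows in patterns.values():
            o = np.where(~key)[0]
            mi = np.where(key)[0]
            Xr = X[rows]
            filled = Xr.copy()
            if mi.size:
                if o.size:
                    soo = sigma[np.ix_(o, o)] + ridge * np.eye(o.size)
                    B = np.linalg.solve(soo, sigma[np.ix_(o, mi)]).T
                    cond_mean = mu[mi] + (Xr[:, o] - mu[o]) @ B.T
                    cond_cov = sigma[np.ix_(mi, mi)] - B @ sigma[np.ix_(o, mi)]
                else:
                    cond_mean = np.broadcast_to(mu[mi], (len(rows), mi.size))
                    cond_cov = sigma[np.ix_(mi, mi)]
                filled[:, mi] = cond_mean
                s2[np.ix_(mi, mi)] += len(rows) * cond_cov
            s1 += filled.sum(axis=0)
            s2 += filled.T @ filled
        mu_new = s1 / n
        sigma_new = s2 / n - np.outer(mu_new, mu_new) + ridge * np.eye(p)
        shift = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if shift < tol:
            break
    return mu, sigma


def _conditional_predict(
    X: np.ndarray, mu: np.ndarray, sigma: np.ndarray, ridge: float = 1e-6
) -> np.ndarray:
    """Fill every missing cell of X with its conditional mean under
    N(mu, sigma) given the row's observed cells.

    The conditional mean is the *predicted probability* for a binary
    indicator; the Bernoulli draw downstream supplies the binary residual
    variance, and parameter uncertainty comes from the bootstrap-EM step.
    (Adding latent normal noise here and truncating would pull class-
    conditional probabilities toward 0.5 and attenuate odds ratios.)
    """
    out = X.copy()
    miss = np.isnan(X)
    for key in np.unique(miss, axis=0):
        mi = np.where(key)[0]
        if not mi.size:
            continue
        rows = np.where((miss == key).all(axis=1))[0]
        o = np.where(~key)[0]
        if o.size:
            soo = sigma[np.ix_(o, o)] + ridge * np.eye(o.size)
            B = np.linalg.solve(soo, sigma[np.ix_(o, mi)]).T
            cond_mean = mu[mi] + (X[np.ix_(rows, o)] - mu[o]) @ B.T
        else:
            cond_mean = np.broadcast_to(mu[mi], (rows.size, mi.size)).copy()
        out[np.ix_(rows, mi)] = cond_mean
    return out


# ---------------------------------------------------------------------------
# imputation front end
# ---------------------------------------------------------------------------

def _model_matrix(
    cohort: CohortTable, config: ImputationConfig
) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric matrix for the imputation model.

    Columns: symptoms (0/1/nan), outcome (0/1, complete), then binary-coded
    covariates.  Covariates with any missing value are dropped (only symptom
    states are imputed).  Returns (X, column names, imputable symptom names).
    """
    df = cohort.df
    cols: dict[str, np.ndarray] = {}
    imputable: list[str] = []
    for s in cohort.symptom_names:
        v = df[s].astype("Float64").to_numpy(dtype=float, na_value=np.nan)
        if np.isnan(v).all():
            warnings.warn(
                f"symptom {s!r} is unrecorded in every row; excluded from the "
                "imputation model and imputed from its class margin",
                stacklevel=3,
            )
        cols[s] = v
        if np.isnan(v).any():
            imputable.append(s)
    cols["outcome"] = (df["outcome"] == OUTCOME_POSITIVE).to_numpy(dtype=float)

    wanted = (
        config.variables
        if config.variables is not None
        else tuple(c for c in _BINARY_COVARIATE_CODES if c in df.columns)
    )
    for c in wanted:
        if c not in df.columns:
            raise KeyError(f"imputation variable {c!r} not in cohort")
        codes = _BINARY_COVARIATE_CODES.get(c)
        if codes is None:
            raise ValueError(f"covariate {c!r} has no binary encoding")
        v = df[c].map(codes).to_numpy(dtype=float, na_value=np.nan)
        if not np.isnan(v).any():
            cols[c] = v
    names = list(cols)
    return np.column_stack([cols[c] for c in names]), names, imputable


def _fill_from_latent(
    predicted: np.ndarray, miss: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli draws from predicted probabilities truncated to [0, 1]."""
    prob = np.clip(predicted, 0.0, 1.0)
    draws = (rng.random(predicted.shape) < prob).astype(float)
    return np.where(miss, draws, predicted)


def impute(cohort: CohortTable, config: ImputationConfig) -> list[CohortTable]:
    """Produce ``config.m`` completed cohorts (no unrecorded symptom states).

    Recorded states are never altered; the outcome is never imputed.  A
    cohort with no missing symptom states returns m identical copies.
    """
    X, names, imputable = _model_matrix(cohort, config)
    if not imputable:
        return [cohort.copy() for _ in range(config.m)]

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.m)
    completed: list[CohortTable] = []
    for child in children:
        rng = np.random.default_rng(child)
        if config.method == "em_bootstrap_latent_normal":
            boot = X[rng.integers(0, len(X), len(X))]
            mu, sigma = _em_mvn(boot, config.em_max_iter, config.em_tol)
            predicted = _conditional_predict(X, mu, sigma)
            filled = _fill_from_latent(predicted, np.isnan(X), rng)
        elif config.method == "logistic_cc":
            filled = _chained_logistic(X, names, rng)
        else:
            raise ValueError(f"unknown imputation method {config.method!r}")
        df = cohort.df.copy()
        for j, name in enumerate(names):
            if name in cohort.symptom_names:
                col = df[name].copy()
                mask = col.isna()
                if mask.any():
                    col[mask] = pd.array(
                        filled[mask.to_numpy(), j] > 0.5, dtype="boolean"
                    )
                df[name] = col
        completed.append(
            replace(cohort, df=df, provenance=cohort.provenance + "+imputed")
        )
    return completed


def _chained_logistic(
    X: np.ndarray, names: list[str], rng: np.random.Generator, sweeps: int = 3
) -> np.ndarray:
    """Fallback: chained logistic regression with approximate posterior draws
    of the coefficients; initialised from outcome-conditional margins."""
    import statsmodels.api as sm

    out = X.copy()
    miss = np.isnan(X)
    outcome = X[:, names.index("outcome")]
    # initial fill: class-conditional observed mean (0.5 if never observed)
    for j in range(X.shape[1]):
        if not miss[:, j].any():
            continue
        for cls in (0.0, 1.0):
            sel = miss[:, j] & (outcome == cls)
            obs = ~miss[:, j] & (outcome == cls)
            p = X[obs, j].mean() if obs.any() else 0.5
            out[sel, j] = (rng.random(sel.sum()) < p).astype(float)

    for _ in range(sweeps):
        for j in range(X.shape[1]):
            mj = miss[:, j]
            if not mj.any() or mj.all():
                continue
            pred = np.delete(out, j, axis=1)
            design = np.column_stack([np.ones(len(out)), pred])
            try:
                fit = sm.GLM(
                    X[~mj, j], design[~mj], family=sm.families.Binomial()
                ).fit(maxiter=50)
                beta = np.asarray(fit.params, dtype=float)
                cov = np.asarray(fit.cov_params(), dtype=float)
                cov = (cov + cov.T) / 2 + 1e-10 * np.eye(len(beta))
                beta = beta + np.linalg.cholesky(cov) @ rng.standard_normal(len(beta))
                eta = design[mj] @ beta
                p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            except Exception:  # separation or non-convergence: marginal fallback
                p = np.full(mj.sum(), X[~mj, j].mean())
            out[mj, j] = (rng.random(mj.sum()) < p).astype(float)
    return out


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------

def pool_profiles(
    profiles: Sequence[DiagnosticProfile], alpha: float = 0.05
) -> PooledProfile:
    """Combine per-completion diagnostic profiles with Rubin's rules.

    Each statistic is pooled on its transformed scale (log for ratios, logit
    for proportions): point = back-transformed mean of the m estimates,
    total variance = within + (1 + 1/m) * between, and the CI uses the
    Barnard-Rubin small-sample degrees of freedom.  Degenerate estimates are
    continuity-adjusted before transforming and flagged in the method label.
    """
    if len(profiles) < 2:
        raise ValueError("pooling requires at least two profiles")
    sizes = {p.n_used for p in profiles}
    if len(sizes) != 1:
        raise ValueError(f"profiles computed on unequal sizes: {sorted(sizes)}")
    m = len(profiles)
    n = profiles[0].n_used

    estimates: dict[str, EstimateWithCI] = {}
    within: dict[str, float] = {}
    between: dict[str, float] = {}
    total: dict[str, float] = {}
    for stat in STATISTICS:
        qs, us, flagged = [], [], False
        for p in profiles:
            q, u, adj = transformed_estimate(p.table, stat)
            qs.append(q)
            us.append(u)
            flagged |= adj
        qbar = float(np.mean(qs))
        w = float(np.mean(us))
        b = float(np.var(qs, ddof=1))
        t = w + (1 + 1 / m) * b
        df = _barnard_rubin_df(m, w, b, t, df_com=n - 1)
        half = stats.t.ppf(1 - alpha / 2, df) * math.sqrt(t)
        scale = "proportion" if stat not in ("odds_ratio", "lr_pos", "lr_neg") else "ratio"
        method = f"rubin(m={m})" + ("+continuity0.5" if flagged else "")
        estimates[stat] = EstimateWithCI(
            back_transform(stat, qbar),
            back_transform(stat, qbar - half),
            back_transform(stat, qbar + half),
            scale,
            method,
        )
        within[stat], between[stat], total[stat] = w, b, t
    return PooledProfile(
        estimates=estimates, within_var=within, between_var=between,
        total_var=total, m=m, n_used=n,
    )


def _barnard_rubin_df(m: int, w: float, b: float, t: float, df_com: float) -> float:
    """Barnard-Rubin adjusted degrees of freedom for the pooled t interval."""
    lam = (1 + 1 / m) * b / t if t > 0 else 0.0
    df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
    if lam <= 0:
        return df_obs
    df_old = (m - 1) / lam**2
    return 1.0 / (1.0 / df_old + 1.0 / df_obs)


def pooled_profile_for(
    completed: Sequence[CohortTable], predictor, alpha: float = 0.05
) -> PooledProfile:
    """Profile a predictor on each completed cohort and Rubin-pool."""
    profs = [
        diagnostic_profile(cross_tabulate(ct, predictor), alpha=alpha)
        for ct in completed
    ]
    return pool_profiles(profs, alpha=alpha)


def stacked_profile(
    completed: Sequence[CohortTable], predictor, alpha: float = 0.05
) -> DiagnosticProfile:
    """Alternative to Rubin pooling: profile the m completed datasets stacked
    into one table (point estimates average naturally; CIs are anti-
    conservative since rows repeat m times).  Exposed for sensitivity
    analysis, not the default."""
    tables = [cross_tabulate(ct, predictor) for ct in completed]
    from .metrics import TwoByTwo

    stacked = TwoByTwo(
        sum(t.a for t in tables), sum(t.b for t in tables),
        sum(t.c for t in tables), sum(t.d for t in tables),
    )
    return diagnostic_profile(stacked, alpha=alpha)
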