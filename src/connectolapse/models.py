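"""Longitudinal linear mixed-effects group contrasts with per-family FDR.

Per connection, strength is modelled over time by

    Y_ij = alpha + beta t_ij + gamma group_i + delta group_i t_ij
           + theta' X_i + a_i + b_i t_ij + e_ij

with time in years since baseline (t = visit - 1), group coded 0 = control /
1 = disease, baseline covariates X (age, sex, site, education), joint-normal
per-subject random intercept and slope (a_i, b_i) and i.i.d. normal errors.
Estimation is maximum likelihood (not REML); the contrasts of interest are
gamma (baseline group difference) and delta (group difference in rate of
change), tested two-sided via z = estimate / SE.  Missing visits enter the
likelihood as ignorable missingness.

A cognition variant replaces the group dummy by a continuous standardized
baseline cognitive composite c_i (terms gamma c_i + delta c_i t_ij) with
covariates age, site, education, CAG and CAG-by-time.

Multiple-comparison control is Benjamini-Hochberg FDR, applied separately
within each connection-subtype family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from connectolapse.io import LongDataset, build_long_table
from connectolapse.subtypes import SubtypeConnection, aggregate_strength

__all__ = ["Effect", "LmerFit", "FdrResult", "fit_group_lmer", "fit_cognition_lmer", "fdr_bh", "run_subtype_models"]


@dataclass(frozen=True)
class Effect:
    estimate: float
    se: float

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p(self) -> float:
        # clamp away underflow to keep p in (0, 1]
        return float(max(2.0 * stats.norm.sf(abs(self.z)), np.finfo(float).tiny))


@dataclass
class LmerFit:
    """Fixed-effect estimates of the longitudinal model, with z-ratios."""

    alpha: Effect  # control intercept (or overall intercept, cognition variant)
    beta: Effect  # control slope
    gamma: Effect  # group (or cognition) intercept difference
    delta: Effect  # group (or cognition) slope difference
    covariates: dict[str, Effect]
    cov_re: np.ndarray  # random-effect covariance (2x2, or 1x1 after fallback)
    converged: bool
    fallback: str = "full"  # "full" or "intercept_only"

    def effects(self) -> dict[str, Effect]:
        return {"alpha": self.alpha, "beta": self.beta, "gamma": self.gamma, "delta": self.delta, **self.covariates}


@dataclass
class FdrResult:
    family: str
    pvalues: np.ndarray
    qvalues: np.ndarray


def _check_design(df: pd.DataFrame, columns: Sequence[str]) -> None:
    for col in columns:
        if df[col].nunique() < 2:
            raise ValueError(f"collinear design: covariate {col!r} is constant")


def _try_fit(df: pd.DataFrame, formula: str, re_formula: str):
    """One structure, several optimizers: fast lbfgs first, then the default chain."""
    model = smf.mixedlm(formula, df, groups=df["subject"], re_formula=re_formula)
    for kwargs in ({"method": "lbfgs"}, {}):
        try:
            result = model.fit(reml=False, maxiter=500, **kwargs)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if result.converged and np.isfinite(result.bse_fe).all():
            return result
    return None


def _fit_mixedlm(df: pd.DataFrame, formula: str) -> tuple["smf.mixedlm", bool, str, np.ndarray]:
    """Fit with random intercept+slope; fall back to intercept-only."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        result = _try_fit(df, formula, "~time")
        if result is not None:
            return result, True, "full", np.asarray(result.cov_re)
        result = _try_fit(df, formula, "1")
        if result is not None:
            return result, True, "intercept_only", np.asarray(result.cov_re)
        # last resort: report the non-converged intercept-only fit, flagged
        model = smf.mixedlm(formula, df, groups=df["subject"], re_formula="1")
        result = model.fit(reml=False, maxiter=500)
        return result, False, "intercept_only", np.asarray(result.cov_re)


def _extract(result, name: str) -> Effect:
    return Effect(float(result.fe_params[name]), float(result.bse_fe[name]))


def fit_group_lmer(
    long_table: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "site", "education"),
) -> LmerFit:
    """Fit the group-contrast model to one connection's long table.

    ``long_table`` needs columns subject, time, group ('control'/'preHD'),
    value, and the requested covariates.  Categorical covariates (sex, site)
    are reference-coded; the group contrasts are invariant to the coding.
    """
    df = long_table.copy()
    if df["group"].nunique() < 2:
        raise ValueError("both groups must be present")
    for g in ("control", "preHD"):
        if df.loc[df["group"] == g, "subject"].nunique() < 2:
            raise ValueError(f"need >= 2 subjects in group {g!r}")
    df["grp"] = (df["group"] == "preHD").astype(int)
    _check_design(df, covariates)
    terms = ["time", "grp", "time:grp"]
    for cov in covariates:
        terms.append(f"C({cov})" if df[cov].dtype == object else cov)
    formula = "value ~ " + " + ".join(terms)
    result, converged, fallback, cov_re = _fit_mixedlm(df, formula)
    named = {"Intercept": "alpha", "time": "beta", "grp": "gamma", "time:grp": "delta"}
    main = {v: _extract(result, k) for k, v in named.items()}
    covs = {k: _extract(result, k) for k in result.fe_params.index if k not in named}
    return LmerFit(
        alpha=main["alpha"], beta=main["beta"], gamma=main["gamma"], delta=main["delta"],
        covariates=covs, cov_re=cov_re, converged=converged, fallback=fallback,
    )


def fit_cognition_lmer(
    long_table: pd.DataFrame,
    covariates: Sequence[str] = ("age", "site", "education"),
) -> LmerFit:
    """Cognition variant: continuous baseline composite replaces the group dummy.

    Restricted to the disease group; covariates are age, site, education, CAG
    and the CAG-by-time interaction.
    """
    df = long_table.loc[long_table["group"] == "preHD"].copy()
    if df.empty:
        raise ValueError("no disease-group rows")
    if df["cognition"].isna().any():
        raise ValueError("cognition must be available for every subject")
    if df["cognition"].nunique() < 2:
        raise ValueError("collinear design: covariate 'cognition' is constant")
    _check_design(df, [*covariates, "cag"])
    terms = ["time", "cognition", "cognition:time", "cag", "cag:time"]
    for cov in covariates:
        terms.append(f"C({cov})" if df[cov].dtype == object else cov)
    formula = "value ~ " + " + ".join(terms)
    result, converged, fallback, cov_re = _fit_mixedlm(df, formula)
    named = {"Intercept": "alpha", "time": "beta", "cognition": "gamma", "cognition:time": "delta"}
    main = {v: _extract(result, k) for k, v in named.items()}
    covs = {k: _extract(result, k) for k in result.fe_params.index if k not in named}
    return LmerFit(
        alpha=main["alpha"], beta=main["beta"], gamma=main["gamma"], delta=main["delta"],
        covariates=covs, cov_re=cov_re, converged=converged, fallback=fallback,
    )


def fdr_bh(pvals: Sequence[float], family: str = "") -> FdrResult:
    """Benjamini-Hochberg step-up adjusted q-values within one family."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return FdrResult(family=family, pvalues=p, qvalues=q)


def run_subtype_models(
    dataset: LongDataset,
    connections: Sequence[SubtypeConnection],
    covariates: Sequence[str] = ("age", "sex", "site", "education"),
) -> pd.DataFrame:
    """Fit the group model per subtype-level connection and FDR-correct.

    Returns one row per connection with gamma/delta estimates, SEs, z, p and
    BH q-values computed within each subtype family (separately for the
    intercept and slope contrasts).
    """
    rows = []
    for conn in connections:
        strengths = {
            (obs.subject_id, obs.visit): aggregate_strength(obs.W, conn)
            for obs in dataset.observations
        }
        table = build_long_table(dataset, strengths)
        fit = fit_group_lmer(table, covariates=covariates)
        rows.append(
            {
                "connection": conn.name,
                "subtype": conn.subtype.value,
                "gamma_est": fit.gamma.estimate,
                "gamma_se": fit.gamma.se,
                "gamma_z": fit.gamma.z,
                "gamma_p": fit.gamma.p,
                "delta_est": fit.delta.estimate,
                "delta_se": fit.delta.se,
                "delta_z": fit.delta.z,
                "delta_p": fit.delta.p,
                "converged": fit.converged,
                "fallback": fit.fallback,
            }
        )
    df = pd.DataFrame(rows)
    for effect in ("gamma", "delta"):
        df[f"{effect}_q"] = np.nan
        for subtype, idx in df.groupby("subtype").groups.items():
            res = fdr_bh(df.loc[idx, f"{effect}_p"], family=f"{subtype}:{effect}")
            df.loc[idx, f"{effect}_q"] = res.qvalues
    return df
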