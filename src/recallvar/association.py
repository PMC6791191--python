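"""Set-wise multivariate tests and univariate follow-up models.

The analysis compares food-secure and food-insecure participants on three
fixed sets of consumption variables (amounts, intraday pattern, interday
variability), first with a multivariate test of the FI term over each set
(Pillai's trace by default, Wilks' lambda available) and then with
univariate general linear models per outcome, simple and adjusted for
age, income (poverty-income ratio), education, ethnicity and presence of
children. The adjusted univariate estimates, divided by each outcome's
marginal SD, form the standardized forest table.

Fits are unweighted by default; a survey weight turns every fit into
weighted least squares with model-based standard errors (no design-based
variance estimation — a documented limitation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from . import schema as S

__all__ = ["MANOVAResult", "GLMResult", "build_design", "fit_manova",
           "fit_univariate", "standardize_estimates", "run_table2"]


@dataclass(frozen=True)
class MANOVAResult:
    statistic: str
    value: float      # Pillai's trace V or Wilks' lambda
    f_value: float
    df1: float
    df2: float
    p_value: float
    n_used: int


@dataclass(frozen=True)
class GLMResult:
    outcome: str
    b: float          # insecure minus secure (secure = reference)
    se: float
    p_value: float
    n_used: int
    adjusted: bool


def build_design(data: pd.DataFrame, predictor: str = S.FI_BINARY,
                 covariates: Sequence[str] = ()) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix with intercept, predictor contrasts, covariate terms.

    Binary FI enters as an insecure-vs-secure indicator; a four-level FI
    enters as three indicators against the secure reference. Education and
    ethnicity expand to indicator contrasts against their first observed
    level; other covariates enter linearly.
    """
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    if predictor == S.FI_BINARY or set(data[predictor].dropna().unique()) <= {
            S.SECURE, S.INSECURE}:
        X[f"{predictor}[{S.INSECURE}]"] = (
            data[predictor] == S.INSECURE).astype(float)
    else:
        levels = [l for l in pd.unique(data[predictor]) if l != S.SECURE]
        # keep a deterministic order with the secure level as reference
        for level in sorted(map(str, levels)):
            X[f"{predictor}[{level}]"] = (
                data[predictor].astype(str) == level).astype(float)
    pred_cols = [c for c in X.columns if c != "const"]
    for cov in covariates:
        if cov in S.CATEGORICAL_COVARIATES or data[cov].dtype == object:
            dummies = pd.get_dummies(data[cov].astype("category"),
                                     prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = data[cov].astype(float)
    return X, pred_cols


def _complete_cases(data: pd.DataFrame, columns: Sequence[str],
                    weights: str | None) -> pd.DataFrame:
    cols = list(dict.fromkeys(columns)) + ([weights] if weights else [])
    return data.dropna(subset=cols)


def fit_manova(data: pd.DataFrame, outcomes: Sequence[str],
               predictor: str = S.FI_BINARY, covariates: Sequence[str] = (),
               weights: str | None = None,
               statistic: str = "pillai") -> MANOVAResult:
    """Multivariate linear model of an outcome set; test of the FI term.

    Complete cases across outcomes, predictor and covariates. The hypothesis
    SSCP for the predictor contrast(s) is compared with the residual SSCP via
    Pillai's trace (default) or Wilks' lambda with their standard F
    approximations. For a two-group predictor the two statistics give the
    identical F test.
    """
    if statistic not in ("pillai", "wilks"):
        raise ValueError(f"unknown statistic {statistic!r}")
    df = _complete_cases(data, list(outcomes) + [predictor] + list(covariates),
                         weights)
    if df[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has fewer than two levels "
                         "in the complete-case sample")
    X, pred_cols = build_design(df, predictor, covariates)
    Xm = X.to_numpy(float)
    Y = df[list(outcomes)].to_numpy(float)
    n, p = Y.shape
    q = len(pred_cols)
    if weights is not None:
        w = np.sqrt(df[weights].to_numpy(float))
        Xm = Xm * w[:, None]
        Y = Y * w[:, None]
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        raise ValueError("singular design matrix (collinear covariates)")
    if n <= Xm.shape[1] + p:
        raise ValueError("too few complete cases for the multivariate model")

    XtX = Xm.T @ Xm
    B = np.linalg.solve(XtX, Xm.T @ Y)
    resid = Y - Xm @ B
    E = resid.T @ resid
    idx = [X.columns.get_loc(c) for c in pred_cols]
    L = np.zeros((q, Xm.shape[1]))
    for i, j in enumerate(idx):
        L[i, j] = 1.0
    M = L @ np.linalg.inv(XtX) @ L.T
    LB = L @ B
    H = LB.T @ np.linalg.solve(M, LB)

    dfe = n - Xm.shape[1]
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (dfe - p - 1) / 2.0
    if statistic == "pillai":
        V = float(np.trace(np.linalg.solve(H + E, H)))
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        F = (df2 / df1) * V / (s - V)
        value = V
    else:
        lam = float(np.linalg.det(E) / np.linalg.det(H + E))
        r = dfe - (p - q + 1) / 2.0
        u = (p * q - 2) / 4.0
        tt = (np.sqrt((p ** 2 * q ** 2 - 4) / (p ** 2 + q ** 2 - 5))
              if p ** 2 + q ** 2 - 5 > 0 else 1.0)
        df1 = p * q
        df2 = r * tt - 2 * u
        F = ((1 - lam ** (1 / tt)) / lam ** (1 / tt)) * df2 / df1
        value = lam
    pval = float(st.f.sf(F, df1, df2))
    return MANOVAResult(statistic, value, float(F), float(df1), float(df2),
                        pval, n)


def fit_univariate(data: pd.DataFrame, outcome: str,
                   predictor: str = S.FI_BINARY, covariates: Sequence[str] = (),
                   weights: str | None = None) -> GLMResult:
    """Linear model of one outcome on FI (+ covariates); B is insecure - secure."""
    df = _complete_cases(data, [outcome, predictor] + list(covariates), weights)
    if df[predictor].nunique() < 2:
        raise ValueError(f"predictor {predictor!r} has fewer than two levels "
                         "in the complete-case sample")
    X, pred_cols = build_design(df, predictor, covariates)
    y = df[outcome].astype(float)
    if weights is None:
        model = sm.OLS(y, X.astype(float))
    else:
        model = sm.WLS(y, X.astype(float), weights=df[weights].astype(float))
    res = model.fit()
    term = pred_cols[0]
    return GLMResult(outcome=outcome, b=float(res.params[term]),
                     se=float(res.bse[term]), p_value=float(res.pvalues[term]),
                     n_used=int(res.nobs), adjusted=bool(covariates))


def standardize_estimates(glm_results: Sequence[GLMResult],
                          data: pd.DataFrame) -> pd.DataFrame:
    """Forest table: B / marginal outcome SD, 95% CI, sorted by |estimate|.

    The FI predictor stays a two-level contrast, so the standardized estimate
    is the group difference in outcome-SD units (the outcome SD is taken over
    all non-missing values in the analysis sample).
    """
    rows = []
    for r in glm_results:
        sd = float(data[r.outcome].std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"outcome {r.outcome} has zero or undefined SD")
        rows.append({
            "outcome": r.outcome,
            "estimate": r.b / sd,
            "ci_low": (r.b - 1.96 * r.se) / sd,
            "ci_high": (r.b + 1.96 * r.se) / sd,
            "p_value": r.p_value,
        })
    out = pd.DataFrame(rows)
    return (out.reindex(out["estimate"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True))


def run_table2(data: pd.DataFrame, predictor: str = S.FI_BINARY,
               covariates: Sequence[str] = tuple(S.COVARIATES),
               weights: str | None = None,
               statistic: str = "pillai") -> pd.DataFrame:
    """Simple and adjusted MANOVA + univariate results for all three sets.

    Returns a long-format frame with one MANOVA row per set and one row per
    outcome variable, for the unadjusted and the adjusted models.
    """
    records = []
    for adjusted, covs in ((False, ()), (True, tuple(covariates))):
        label = "adjusted" if adjusted else "unadjusted"
        for set_name, outcomes in S.OUTCOME_SETS.items():
            man = fit_manova(data, outcomes, predictor, covs, weights, statistic)
            records.append({
                "model": label, "set": set_name, "outcome": "(MANOVA)",
                "b": np.nan, "se": np.nan, "F": man.f_value, "df1": man.df1,
                "df2": man.df2, "p_value": man.p_value, "n": man.n_used,
            })
            for outcome in outcomes:
                g = fit_univariate(data, outcome, predictor, covs, weights)
                records.append({
                    "model": label, "set": set_name, "outcome": outcome,
                    "b": g.b, "se": g.se, "F": np.nan, "df1": np.nan,
                    "df2": np.nan, "p_value": g.p_value, "n": g.n_used,
                })
    return pd.DataFrame(records)
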