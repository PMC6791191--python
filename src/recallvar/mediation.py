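"""Mediator screening and the multiple-mediation decomposition of the
FI -> BMI association.

The path system is the saturated recursive linear model: each mediator is
regressed on FI (plus covariates) for the a-paths, and BMI on FI, all
mediators and covariates for the direct effect c' and the b-paths. Because
every equation is fitted by least squares on the identical complete-case
sample, the decomposition

    c  =  c' + sum_i a_i * b_i

holds exactly (linear path algebra), so the total effect is computed from
the identity and the proportions mediated sum exactly. Indirect-effect
standard errors use the delta method (Sobel), se = sqrt(a^2 se_b^2 +
b^2 se_a^2); a percentile bootstrap over participants is available as an
alternative inference method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema as S
from .association import build_design

__all__ = ["MediatorScreenRow", "MediationResult", "screen_mediators",
           "fit_multiple_mediation"]


@dataclass(frozen=True)
class MediatorScreenRow:
    variable: str
    b: float                 # coefficient on BMI, adjusted
    se: float
    p_value: float
    fi_effect: float         # adjusted FI effect on the variable (sign source)
    direction_consistent: bool
    candidate: bool          # p < alpha and direction-consistent
    n_used: int


@dataclass(frozen=True)
class MediationResult:
    mediators: tuple[str, ...]
    a: np.ndarray
    se_a: np.ndarray
    b: np.ndarray
    se_b: np.ndarray
    indirect: np.ndarray
    se_indirect: np.ndarray
    z_indirect: np.ndarray
    p_indirect: np.ndarray
    direct: float            # c'
    se_direct: float
    total: float             # c = c' + sum a_i b_i (identity)
    se_total: float
    z_total: float
    p_total: float
    proportion: np.ndarray   # indirect_i / c
    proportion_total: float
    n_used: int
    bootstrap_ci: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per mediator plus direct/total summary rows."""
        rows = []
        for i, m in enumerate(self.mediators):
            rows.append({
                "path": m, "a": self.a[i], "se_a": self.se_a[i],
                "b": self.b[i], "se_b": self.se_b[i],
                "effect": self.indirect[i], "se": self.se_indirect[i],
                "z": self.z_indirect[i], "p_value": self.p_indirect[i],
                "proportion_pct": 100.0 * self.proportion[i],
            })
        rows.append({"path": "direct (c')", "effect": self.direct,
                     "se": self.se_direct,
                     "proportion_pct": 100.0 * (1 - self.proportion_total)})
        rows.append({"path": "total (c)", "effect": self.total,
                     "se": self.se_total, "z": self.z_total,
                     "p_value": self.p_total, "proportion_pct": 100.0})
        return pd.DataFrame(rows)


def screen_mediators(data: pd.DataFrame, candidate_vars: Sequence[str],
                     fi_effects: dict[str, float],
                     covariates: Sequence[str] = tuple(S.COVARIATES),
                     outcome: str = S.BMI, alpha: float = 0.05,
                     weights: str | None = None) -> pd.DataFrame:
    """Adjusted BMI model per candidate; flag significance and direction.

    ``candidate_vars`` are the variables already significantly predicted by
    FI after adjustment, and ``fi_effects`` their adjusted FI coefficients.
    A variable is a candidate mediator when it predicts BMI at ``alpha`` and
    sign(B_on_BMI) x sign(FI effect) > 0, i.e. the implied indirect path has
    the same sign as the (positive) FI-BMI association.
    """
    rows = []
    for var in candidate_vars:
        # ordinary adjusted linear model: outcome ~ var + covariates
        df = data.dropna(subset=[outcome, var, *covariates]
                         + ([weights] if weights else []))
        X = pd.DataFrame(index=df.index)
        X["const"] = 1.0
        X[var] = df[var].astype(float)
        Xcov, _ = build_design(df.assign(_null=S.SECURE), "_null", covariates)
        X = pd.concat([X, Xcov.drop(columns=["const", f"_null[{S.INSECURE}]"])],
                      axis=1)
        if weights is None:
            fit = sm.OLS(df[outcome].astype(float), X).fit()
        else:
            fit = sm.WLS(df[outcome].astype(float), X,
                         weights=df[weights].astype(float)).fit()
        b = float(fit.params[var])
        fi_b = float(fi_effects[var])
        consistent = np.sign(b) * np.sign(fi_b) > 0
        rows.append(MediatorScreenRow(
            variable=var, b=b, se=float(fit.bse[var]),
            p_value=float(fit.pvalues[var]), fi_effect=fi_b,
            direction_consistent=bool(consistent),
            candidate=bool(consistent and fit.pvalues[var] < alpha),
            n_used=int(fit.nobs)))
    return pd.DataFrame([r.__dict__ for r in rows])


def _path_fits(df: pd.DataFrame, predictor: str, mediators: Sequence[str],
               outcome: str, covariates: Sequence[str],
               weights: str | None):
    """a-path, outcome and total-effect OLS/WLS fits on one common sample."""
    X_base, pred_cols = build_design(df, predictor, covariates)
    term = pred_cols[0]
    w = df[weights].astype(float) if weights else None

    def fit(y, X):
        return (sm.OLS(y, X).fit() if w is None
                else sm.WLS(y, X, weights=w).fit())

    a = np.empty(len(mediators))
    se_a = np.empty(len(mediators))
    for i, m in enumerate(mediators):
        r = fit(df[m].astype(float), X_base)
        a[i], se_a[i] = r.params[term], r.bse[term]
    X_out = pd.concat([X_base, df[list(mediators)].astype(float)], axis=1)
    out_fit = fit(df[outcome].astype(float), X_out)
    tot_fit = fit(df[outcome].astype(float), X_base)
    b = out_fit.params[list(mediators)].to_numpy(float)
    se_b = out_fit.bse[list(mediators)].to_numpy(float)
    return (a, se_a, b, se_b, float(out_fit.params[term]),
            float(out_fit.bse[term]), float(tot_fit.bse[term]), term)


def fit_multiple_mediation(data: pd.DataFrame, mediators: Sequence[str],
                           predictor: str = S.FI_BINARY, outcome: str = S.BMI,
                           covariates: Sequence[str] = (),
                           weights: str | None = None,
                           inference: str = "delta", n_boot: int = 1000,
                           seed: int | None = None,
                           ) -> MediationResult:
    """Fit the multiple-mediation path system and decompose the total effect.

    Complete cases across predictor, mediators, outcome and covariates. The
    total effect is assembled from the decomposition identity; its standard
    error comes from the separate total-effect regression on the same sample
    (whose point estimate coincides exactly with the identity). With
    ``inference="bootstrap"``, participants are resampled ``n_boot`` times
    for percentile CIs of the indirect effects and proportions.
    """
    if inference not in ("delta", "bootstrap"):
        raise ValueError(f"unknown inference method {inference!r}")
    mediators = tuple(mediators)
    cols = [predictor, outcome, *mediators, *covariates]
    df = data.dropna(subset=cols + ([weights] if weights else [])).copy()
    corr = df[list(mediators)].corr().to_numpy()
    if np.linalg.matrix_rank(corr, tol=1e-10) < len(mediators):
        raise ValueError("collinear mediators")
    (a, se_a, b, se_b, direct, se_direct, se_total, _term) = _path_fits(
        df, predictor, mediators, outcome, covariates, weights)

    indirect = a * b
    se_ind = np.sqrt(a ** 2 * se_b ** 2 + b ** 2 * se_a ** 2)
    z_ind = indirect / se_ind
    from scipy.stats import norm
    p_ind = 2 * norm.sf(np.abs(z_ind))
    total = direct + float(indirect.sum())
    z_total = total / se_total
    p_total = 2 * norm.sf(abs(z_total))
    if abs(total) < 1e-8:
        import warnings
        warnings.warn("total effect ~ 0; proportions mediated are undefined")
        proportion = np.full(len(mediators), np.nan)
        prop_total = np.nan
    else:
        proportion = indirect / total
        prop_total = float(indirect.sum() / total)

    boot_ci: dict = {}
    if inference == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = np.empty((n_boot, len(mediators) + 2))
        idx = np.arange(len(df))
        for rep in range(n_boot):
            take = rng.choice(idx, size=len(idx), replace=True)
            rb = df.iloc[take]
            ab, _, bb, _, db, _, _, _ = _path_fits(
                rb.reset_index(drop=True), predictor, mediators, outcome,
                covariates, weights)
            ind = ab * bb
            tot = db + ind.sum()
            stats[rep] = np.concatenate([ind, [tot, ind.sum() / tot]])
        lo, hi = np.percentile(stats, [2.5, 97.5], axis=0)
        boot_ci = {
            "indirect": {m: (lo[i], hi[i]) for i, m in enumerate(mediators)},
            "total": (lo[-2], hi[-2]),
            "proportion_total": (lo[-1], hi[-1]),
        }
    return MediationResult(
        mediators=mediators, a=a, se_a=se_a, b=b, se_b=se_b,
        indirect=indirect, se_indirect=se_ind, z_indirect=z_ind,
        p_indirect=p_ind, direct=direct, se_direct=se_direct, total=total,
        se_total=se_total, z_total=float(z_total), p_total=float(p_total),
        proportion=proportion, proportion_total=prop_total,
        n_used=len(df), bootstrap_ci=boot_ci)
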