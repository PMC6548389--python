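"""Covariate-adjusted differential abundance with empirical-Bayes moderation.

For each protein, log2 MoM values of the one-sample-per-patient interval view
are regressed on group (case vs control) plus optional maternal covariates
(BMI, smoking, age, nulliparity).  Per-protein residual variances are shrunk
toward a common prior estimated across the panel: sample variances are
modeled as scaled inverse-chi-square around ``s0^2`` with ``d0`` prior
degrees of freedom, estimated in closed form by matching the moments of the
log sample variances through the digamma/trigamma relations.  The moderated
statistic ``t = beta / (s_tilde * sqrt(v))`` with
``s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)`` is referred to a t distribution
with ``d0 + d`` degrees of freedom, and Benjamini-Hochberg q-values are
computed within the interval's protein family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cohort import IntervalView
from .errors import ValidationError

COVARIATES = ["BMI", "Smoking", "MaternalAge", "Nulliparity"]


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(beta) -> np.ndarray:
    """Signed linear fold change from a log2 difference.

    ``2**beta`` for increases; ``-2**(-beta)`` for decreases, so negative
    values denote lower levels in cases (magnitude is the down-fold).
    """
    beta = np.asarray(beta, float)
    return np.where(beta >= 0, np.exp2(beta), -np.exp2(-beta))


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    return x


def estimate_variance_prior(s2, df) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching on ``e_g = log s_g^2 - digamma(d/2) + log(d/2)``: under
    the hierarchical model, ``var(e) = trigamma(d0/2) + trigamma(d/2)`` and
    ``mean(e) = log s0^2 + digamma(d0/2) - log(d0/2)``.  When the observed
    spread does not exceed the sampling component, ``d0`` is infinite and
    ``s0^2 = exp(mean(e))``.
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValidationError("variance prior needs at least two positive sample variances")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = len(e)
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t(beta, s2, df, v, d0: float, s0_2: float):
    """Moderated t-statistics, p-values, and posterior variances."""
    beta = np.asarray(beta, float)
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    t = beta / np.sqrt(s2_tilde * np.asarray(v, float))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, s2_tilde


class ModeratedTTest(BaseEstimator):
    """Per-protein moderated t-test of case-control log2 MoM differences.

    ``fit(X, y, covariates=...)`` expects per-patient log2 MoM features and
    binary labels; results (one row per protein) are in ``results_`` and the
    estimated prior in ``d0_`` / ``s0_squared_``.
    """

    def __init__(self, alpha_q: float = 0.1):
        self.alpha_q = alpha_q

    def fit(self, X, y, covariates: pd.DataFrame | None = None) -> "ModeratedTTest":
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"p{i}" for i in range(np.shape(X)[1])
        ]
        Y = np.asarray(X, float)
        y = np.asarray(y, int)
        n = len(y)
        if y.sum() == 0 or y.sum() == n:
            raise ValidationError("both groups must be present")

        design = [np.ones(n), y.astype(float)]
        design_names = ["intercept", "group"]
        self.adjusted_ = False
        if covariates is not None:
            cov = np.asarray(covariates, float)
            if cov.shape[0] != n or not np.all(np.isfinite(cov)):
                warnings.warn(
                    "covariates incomplete for the included patients; "
                    "falling back to the unadjusted model",
                    UserWarning, stacklevel=2,
                )
            else:
                design.extend(list(cov.T))
                design_names.extend(
                    list(covariates.columns)
                    if isinstance(covariates, pd.DataFrame)
                    else [f"c{i}" for i in range(cov.shape[1])]
                )
                self.adjusted_ = True
        D = np.column_stack(design)
        rank = np.linalg.matrix_rank(D)
        if n <= D.shape[1] or rank < D.shape[1]:
            raise ValidationError(
                f"design with {D.shape[1]} parameters cannot be fit on {n} patients"
            )
        df_resid = n - D.shape[1]

        DtD_inv = np.linalg.inv(D.T @ D)
        coefs = DtD_inv @ (D.T @ Y)
        resid = Y - D @ coefs
        s2 = (resid**2).sum(axis=0) / df_resid
        if (s2 <= 0).any():
            raise ValidationError("zero residual variance encountered")
        beta = coefs[1]  # group effect, cases minus controls
        v_group = float(DtD_inv[1, 1])

        d0, s0_2 = estimate_variance_prior(s2, df_resid)
        t, p, s2_tilde = moderated_t(beta, s2, df_resid, v_group, d0, s0_2)
        q = bh_qvalues(p)

        self.d0_ = d0
        self.s0_squared_ = s0_2
        self.df_residual_ = df_resid
        self.design_names_ = design_names
        self.results_ = pd.DataFrame(
            {
                "protein": names,
                "log2_fc": beta,
                "fc": signed_fold_change(beta),
                "s2": s2,
                "s2_moderated": s2_tilde,
                "t": t,
                "p": p,
                "q": q,
                "significant": q < self.alpha_q,
            }
        )
        return self


def fit_moderated(view: IntervalView, covariates: pd.DataFrame | None = None,
                  alpha_q: float = 0.1, log2_input: bool = False) -> ModeratedTTest:
    """Moderated differential abundance for one interval view.

    ``covariates`` is a per-patient table indexed by patient ID with columns
    BMI, Smoking, MaternalAge, Nulliparity; when absent or incomplete the
    model degrades to unadjusted with a warning.
    """
    X = view.X if log2_input else np.log2(view.X)
    X = pd.DataFrame(np.asarray(X, float), columns=view.X.columns)
    cov = None
    if covariates is not None:
        missing = [c for c in COVARIATES if c not in covariates.columns]
        if missing:
            raise ValidationError(f"covariate table is missing column {missing[0]!r}")
        cov = covariates.reindex(view.patients["patient_id"])[COVARIATES]
    return ModeratedTTest(alpha_q=alpha_q).fit(X, view.y, covariates=cov)
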