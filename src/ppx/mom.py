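"""Gestational-age-referenced MoM normalization.

Raw relative-fluorescence abundances are thresholded (values above twice the
98th percentile are reset to that ceiling), log2-transformed, and referenced
against a per-protein control-group mean curve: a cubic regression spline in
gestational age fitted by a linear mixed-effects model with a subject random
intercept.  Every sample is then expressed as a multiple of the mean (MoM),
``MoM = 2**(log2(value) - mu_hat(GA))``, which removes the gestational-age
dependence so samples from different trimesters are comparable.

The random-intercept model ``y_ij = x(GA_ij)' beta + b_i + e_ij`` with
``b_i ~ N(0, tau^2)`` and ``e_ij ~ N(0, sigma^2)`` is fitted by REML,
profiling the variance ratio ``lambda = tau^2 / sigma^2`` down to a
one-dimensional search with closed-form GLS at each candidate ratio.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import LATE_PE_COLUMN, CohortTable
from .errors import ValidationError

_FORMAT_VERSION = 1


def clip_outliers(values, ceiling: float | None = None):
    """Threshold extreme abundances at twice the 98th percentile.

    When ``ceiling`` is given (e.g. recorded from a training dataset) it is
    reused; otherwise it is computed from ``values`` with the
    linear-interpolation quantile estimator.  Returns the clipped vector and
    the ceiling.  An all-zero vector yields ceiling 0 and a warning: such a
    protein carries no signal and is flagged unusable downstream.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValidationError("clip_outliers expects a vector of length >= 2")
    if (values < 0).any():
        raise ValidationError("abundances must be nonnegative")
    if ceiling is None:
        ceiling = 2.0 * float(np.quantile(values, 0.98))
    if ceiling == 0.0:
        warnings.warn("degenerate protein: all abundances are zero", UserWarning, stacklevel=2)
        return np.zeros_like(values), 0.0
    return np.minimum(values, ceiling), float(ceiling)


# -- spline basis -------------------------------------------------------------


def _bspline_design(x, knots, lo, hi, degree=3):
    """Cubic B-spline design matrix with clamped boundary knots.

    ``x`` is clipped to ``[lo, hi]``; the basis has ``len(knots) + degree + 1``
    columns and partitions unity, so the intercept lies in its span.
    """
    x = np.clip(np.asarray(x, dtype=float), lo, hi)
    t = np.r_[[lo] * (degree + 1), np.asarray(knots, float), [hi] * (degree + 1)]
    return BSpline.design_matrix(x, t, degree).toarray()


# -- random-intercept REML ----------------------------------------------------


def _reml_profile(loglam, y, X, starts, sizes):
    """Profiled -2 REML criterion and GLS estimates at a fixed variance ratio."""
    lam = np.exp(loglam)
    c = lam / (1.0 + lam * sizes)  # per-group shrinkage of the group sum
    Xs = np.add.reduceat(X, starts, axis=0)
    ys = np.add.reduceat(y, starts)
    A = X.T @ X - (Xs * c[:, None]).T @ Xs
    b = X.T @ y - Xs.T @ (c * ys)
    beta = np.linalg.solve(A, b)
    r = y - X @ beta
    rs = np.add.reduceat(r, starts)
    quad = float(r @ r - np.sum(c * rs**2))
    n, p = X.shape
    sigma2 = quad / (n - p)
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0 or sigma2 <= 0:
        return np.inf, beta, max(sigma2, 0.0)
    crit = (n - p) * np.log(sigma2) + float(np.sum(np.log1p(lam * sizes))) + logdet_a
    return crit, beta, sigma2


def fit_random_intercept_spline(y, X, groups):
    """REML fit of ``y = X beta + b_group + e`` with a scalar random intercept.

    Returns ``(beta, tau2, sigma2)``.  Rows may be in any order; ``groups``
    is a vector of hashable subject identifiers.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    codes, _ = pd.factorize(np.asarray(groups))
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    starts = np.r_[0, np.flatnonzero(np.diff(codes)) + 1]
    sizes = np.diff(np.r_[starts, len(codes)]).astype(float)

    def objective(loglam):
        return _reml_profile(loglam, y, X, starts, sizes)[0]

    res = minimize_scalar(objective, bounds=(-12.0, 8.0), method="bounded")
    candidates = [res.x, -30.0]  # -30 ~ boundary tau2 = 0
    best = min(candidates, key=objective)
    crit, beta, sigma2 = _reml_profile(best, y, X, starts, sizes)
    if not np.isfinite(crit):
        raise np.linalg.LinAlgError("singular spline design")
    lam = np.exp(best)
    tau2 = lam * sigma2 if best > -29.0 else 0.0
    return beta, tau2, sigma2


# -- reference curve set ------------------------------------------------------


@dataclass
class ReferenceCurveSet:
    """Per-protein control-group GA mean curves with variance components.

    ``coef`` has one row per protein (basis coefficients of the log2-scale
    mean curve); ``tau2``/``sigma2`` are the subject and residual variance
    components; ``ceilings`` are the outlier clip ceilings on the raw scale.
    Degenerate proteins (all-zero or singular fits that could not even take
    an intercept) appear in ``degenerate`` and transform to NaN.
    """

    proteins: list[str]
    knots: np.ndarray
    ga_range: tuple[float, float]
    degree: int
    coef: pd.DataFrame
    tau2: pd.Series
    sigma2: pd.Series
    ceilings: pd.Series
    degenerate: list[str]

    def predict(self, ga_weeks, proteins=None) -> pd.DataFrame:
        """Evaluate the log2 mean curves at the given gestational ages.

        GA values outside the fitted range are clamped to its boundary with
        a warning.
        """
        ga = np.atleast_1d(np.asarray(ga_weeks, dtype=float))
        lo, hi = self.ga_range
        if (ga < lo).any() or (ga > hi).any():
            warnings.warn(
                f"gestational ages outside the fitted range [{lo:.2f}, {hi:.2f}] "
                "were clamped to the boundary",
                UserWarning,
                stacklevel=2,
            )
        basis = _bspline_design(ga, self.knots, lo, hi, self.degree)
        if proteins is None:
            proteins = self.proteins
        missing = [p for p in proteins if p not in self.coef.index]
        if missing:
            raise KeyError(f"protein {missing[0]!r} absent from the reference curves")
        return pd.DataFrame(basis @ self.coef.loc[list(proteins)].T.to_numpy(),
                            columns=list(proteins))

    # JSON round-trip keeps transforms reproducible bit-for-bit.
    def to_json(self) -> str:
        doc = {
            "format_version": _FORMAT_VERSION,
            "degree": self.degree,
            "knots": self.knots.tolist(),
            "ga_range": list(self.ga_range),
            "proteins": self.proteins,
            "coef": {p: self.coef.loc[p].tolist() for p in self.proteins},
            "tau2": self.tau2.to_dict(),
            "sigma2": self.sigma2.to_dict(),
            "ceilings": self.ceilings.to_dict(),
            "degenerate": self.degenerate,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "ReferenceCurveSet":
        doc = json.loads(text)
        if doc.get("format_version") != _FORMAT_VERSION:
            raise ValidationError("unsupported reference-curve document version")
        proteins = doc["proteins"]
        return cls(
            proteins=proteins,
            knots=np.asarray(doc["knots"], float),
            ga_range=tuple(doc["ga_range"]),
            degree=int(doc["degree"]),
            coef=pd.DataFrame([doc["coef"][p] for p in proteins], index=proteins),
            tau2=pd.Series(doc["tau2"]).reindex(proteins),
            sigma2=pd.Series(doc["sigma2"]).reindex(proteins),
            ceilings=pd.Series(doc["ceilings"]).reindex(proteins),
            degenerate=list(doc["degenerate"]),
        )


# -- estimator ----------------------------------------------------------------


class MoMReference(BaseEstimator, TransformerMixin):
    """Transformer mapping raw abundances to gestational-age MoM values.

    Fitting uses only control-group samples for the mean curves (cases never
    influence the reference) while the outlier ceilings are computed over
    all samples of the dataset.  ``transform`` applies the frozen curves to
    any cohort on the same protein panel.

    Parameters
    ----------
    n_knots:
        Number of interior knots of the cubic regression spline, placed at
        equally spaced quantiles of the control samples' GA.
    degree:
        Spline degree (cubic by default).
    min_control_patients:
        Minimum number of distinct control patients required to fit.
    log2_output:
        When True, ``transform`` returns log2 MoM instead of linear MoM.
    """

    def __init__(self, n_knots: int = 3, degree: int = 3,
                 min_control_patients: int = 10, log2_output: bool = False):
        self.n_knots = n_knots
        self.degree = degree
        self.min_control_patients = min_control_patients
        self.log2_output = log2_output

    def _control_mask(self, cohort: CohortTable) -> pd.Series:
        if cohort.labels is not None:
            return cohort.data["ID"].map(cohort.labels).eq("control")
        mask = cohort.data["EarlyPE"] == 0
        if LATE_PE_COLUMN in cohort.data.columns:
            mask &= cohort.data[LATE_PE_COLUMN] == 0
        return mask

    def fit(self, cohort: CohortTable, y=None) -> "MoMReference":
        df = cohort.data
        controls = df.loc[self._control_mask(cohort)]
        n_ctrl = controls["ID"].nunique()
        if n_ctrl < self.min_control_patients:
            raise ValidationError(
                f"reference fit needs >= {self.min_control_patients} control patients, "
                f"got {n_ctrl}"
            )
        ga = controls["GA"].to_numpy(float)
        lo, hi = float(ga.min()), float(ga.max())
        qs = np.linspace(0, 1, self.n_knots + 2)[1:-1]
        knots = np.quantile(ga, qs)
        basis = _bspline_design(ga, knots, lo, hi, self.degree)
        groups = controls["ID"].to_numpy()

        coefs, tau2s, sigma2s, ceilings, degenerate = {}, {}, {}, {}, []
        n_basis = basis.shape[1]
        for prot in cohort.proteins:
            allvals = df[prot].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                _, ceiling = clip_outliers(allvals)
            ceilings[prot] = ceiling
            if ceiling == 0.0:
                warnings.warn(
                    f"protein {prot!r} is all-zero and was flagged unusable",
                    UserWarning, stacklevel=2,
                )
                degenerate.append(prot)
                coefs[prot] = np.full(n_basis, np.nan)
                tau2s[prot] = np.nan
                sigma2s[prot] = np.nan
                continue
            yv = np.log2(np.minimum(controls[prot].to_numpy(float), ceiling))
            if not np.all(np.isfinite(yv)):
                # zeros among otherwise informative values: floor them
                floor = np.min(yv[np.isfinite(yv)]) - 1.0
                yv = np.where(np.isfinite(yv), yv, floor)
            try:
                if np.var(yv) < 1e-12:
                    raise np.linalg.LinAlgError("constant protein")
                beta, tau2, sigma2 = fit_random_intercept_spline(yv, basis, groups)
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"singular spline fit for protein {prot!r}; "
                    "falling back to an intercept-only mean",
                    UserWarning, stacklevel=2,
                )
                # constant curve: partition of unity makes equal coefficients flat
                beta = np.full(n_basis, float(np.mean(yv)))
                tau2, sigma2 = 0.0, float(max(np.var(yv, ddof=1), 1e-12))
            coefs[prot] = beta
            tau2s[prot] = tau2
            sigma2s[prot] = sigma2

        self.curves_ = ReferenceCurveSet(
            proteins=list(cohort.proteins),
            knots=np.asarray(knots, float),
            ga_range=(lo, hi),
            degree=self.degree,
            coef=pd.DataFrame.from_dict(coefs, orient="index").loc[cohort.proteins],
            tau2=pd.Series(tau2s).reindex(cohort.proteins),
            sigma2=pd.Series(sigma2s).reindex(cohort.proteins),
            ceilings=pd.Series(ceilings).reindex(cohort.proteins),
            degenerate=degenerate,
        )
        return self

    def transform(self, cohort: CohortTable) -> CohortTable:
        if not hasattr(self, "curves_"):
            raise ValidationError("MoMReference must be fitted before transform")
        return to_mom(cohort, self.curves_, log2_output=self.log2_output)


# -- functional wrappers ------------------------------------------------------


def fit_reference_curves(controls: CohortTable, n_knots: int = 3,
                         min_control_patients: int = 10) -> ReferenceCurveSet:
    """Fit control-group reference curves; thin wrapper over :class:`MoMReference`."""
    est = MoMReference(n_knots=n_knots, min_control_patients=min_control_patients)
    return est.fit(controls).curves_


def to_mom(cohort: CohortTable, curves: ReferenceCurveSet,
           log2_output: bool = False) -> CohortTable:
    """Express every sample of a cohort in MoM space using frozen curves."""
    missing = [p for p in cohort.proteins if p not in curves.coef.index]
    if missing:
        raise KeyError(f"protein {missing[0]!r} absent from the reference curves")
    ga = cohort.data["GA"].to_numpy(float)
    mu = curves.predict(ga, proteins=cohort.proteins)
    raw = cohort.data[cohort.proteins].to_numpy(float)
    ceil = curves.ceilings.loc[cohort.proteins].to_numpy(float)
    with np.errstate(divide="ignore"):
        log2mom = np.log2(np.minimum(raw, ceil)) - mu.to_numpy()
    out = log2mom if log2_output else np.exp2(log2mom)
    if curves.degenerate:
        cols = [cohort.proteins.index(p) for p in curves.degenerate if p in cohort.proteins]
        out[:, cols] = np.nan
    return cohort.with_abundances(pd.DataFrame(out, columns=cohort.proteins))
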