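"""Single-protein screening and parsimonious LDA panel selection.

Candidate markers are scored one at a time by the partial AUC (FPR < 0.5) of
leave-one-patient-out cross-validated linear-discriminant scores.  Proteins
whose group mean MoM values differ by less than 10% are filtered out first.
Panels are then grown along the pAUC ranking (top-1, top-2, ... top-5) and a
larger panel is kept only when its cross-validated pAUC improves on the
smaller one by at least 0.01 units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import IntervalView
from .errors import ValidationError

_RIDGE = 1e-8


def _ridge_value(trace: float, p: int, ridge: float = _RIDGE) -> float:
    # absolute fallback keeps degenerate (all-constant) folds finite
    return ridge * trace / p if trace > 0 else ridge


def _lda_fit(X: np.ndarray, y: np.ndarray, ridge: float = _RIDGE):
    """Pooled-covariance linear discriminant: weights and centering offset.

    The score of a sample ``x`` is ``w @ (x - (mu0 + mu1) / 2)`` with
    ``w = S^-1 (mu1 - mu0)``; ``S`` is the pooled within-class covariance
    with a small ridge (``1e-8 * trace(S)/p``) for numerical stability.
    """
    X0, X1 = X[y == 0], X[y == 1]
    n0, n1 = len(X0), len(X1)
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    R0, R1 = X0 - mu0, X1 - mu1
    S = (R0.T @ R0 + R1.T @ R1) / (n0 + n1 - 2)
    S = np.atleast_2d(S)
    p = S.shape[0]
    S = S + _ridge_value(float(np.trace(S)), p, ridge) * np.eye(p)
    w = np.linalg.solve(S, mu1 - mu0)
    offset = float(w @ (mu0 + mu1) / 2.0)
    return w, offset


def loocv_scores(X, y, ridge: float = _RIDGE) -> np.ndarray:
    """Out-of-fold LDA score per patient under leave-one-patient-out CV.

    Each score comes from a discriminant refitted on all other patients and
    evaluated on the held-out one; higher scores indicate the case class.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y, int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValidationError("leave-one-out LDA needs at least 2 patients per class")
    n = len(y)
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        w, offset = _lda_fit(X[mask], y[mask], ridge)
        scores[i] = float(X[i] @ w) - offset
        mask[i] = True
    return scores


def _loocv_scores_single_all(X, y, ridge: float = _RIDGE) -> np.ndarray:
    """Single-feature LOOCV LDA scores for every column at once.

    Exact leave-one-out update of class means and pooled variance; agrees
    with :func:`loocv_scores` applied per column up to float round-off.
    Returns an ``(n, p)`` score matrix.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, p = X.shape
    n1 = int(y.sum())
    n0 = n - n1
    s0 = X[y == 0].sum(axis=0)
    s1 = X[y == 1].sum(axis=0)
    ss0 = (X[y == 0] ** 2).sum(axis=0)
    ss1 = (X[y == 1] ** 2).sum(axis=0)
    out = np.empty((n, p))
    for i in range(n):
        xi = X[i]
        if y[i] == 1:
            m1 = (s1 - xi) / (n1 - 1)
            m0 = s0 / n0
            sc1 = (ss1 - xi**2) - (n1 - 1) * m1**2
            sc0 = ss0 - n0 * m0**2
        else:
            m0 = (s0 - xi) / (n0 - 1)
            m1 = s1 / n1
            sc0 = (ss0 - xi**2) - (n0 - 1) * m0**2
            sc1 = ss1 - n1 * m1**2
        s2 = (sc0 + sc1) / (n - 3)
        denom = s2 + np.where(s2 > 0, ridge * s2, ridge)
        w = (m1 - m0) / denom
        out[i] = w * (xi - (m0 + m1) / 2.0)
    return out


# -- ROC / pAUC ---------------------------------------------------------------


@dataclass(frozen=True)
class RocSummary:
    """Empirical ROC metrics: AUC, partial AUC, and sensitivity at a fixed FPR.

    ``pauc`` is the unnormalized area under the ROC over FPR in
    ``[0, fpr_cap]`` (so at most ``fpr_cap``); ``sensitivity`` is the TPR at
    the largest achievable empirical FPR not exceeding ``fpr_target`` — a
    conservative reading that makes the achieved specificity at least
    ``1 - fpr_target``.
    """

    auc: float
    pauc: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr_cap: float = 0.5
    fpr_target: float = 0.10


def _roc_points(scores: np.ndarray, y: np.ndarray):
    """Empirical ROC points at every distinct threshold, plus (0, 0)."""
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    last = np.r_[np.flatnonzero(np.diff(ss) != 0), len(ss) - 1]
    n1 = int(y.sum())
    n0 = len(y) - n1
    tpr = np.r_[0.0, np.cumsum(ys)[last] / n1]
    fpr = np.r_[0.0, np.cumsum(1 - ys)[last] / n0]
    thresholds = np.r_[np.inf, ss[last]]
    return fpr, tpr, thresholds


def _partial_auc(fpr: np.ndarray, tpr: np.ndarray, cap: float) -> float:
    idx = int(np.searchsorted(fpr, cap, side="right"))
    f, t = fpr[:idx], tpr[:idx]
    if f[-1] < cap and idx < len(fpr):
        # linear (trapezoidal) interpolation of the crossing segment
        t_cap = t[-1] + (tpr[idx] - t[-1]) * (cap - f[-1]) / (fpr[idx] - f[-1])
        f = np.r_[f, cap]
        t = np.r_[t, t_cap]
    return float(np.trapezoid(t, f))


def roc_metrics(scores, y, fpr_cap: float = 0.5, fpr_target: float = 0.10) -> RocSummary:
    """Empirical ROC summary with trapezoidal tie handling."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("ROC metrics require both classes to be present")
    fpr, tpr, thr = _roc_points(scores, y)
    auc = float(np.trapezoid(tpr, fpr))
    pauc = _partial_auc(fpr, tpr, fpr_cap)
    ok = np.flatnonzero(fpr <= fpr_target)
    at = ok[-1]
    return RocSummary(
        auc=auc,
        pauc=pauc,
        sensitivity=float(tpr[at]),
        specificity=float(1.0 - fpr[at]),
        threshold=float(thr[at]),
        fpr_cap=fpr_cap,
        fpr_target=fpr_target,
    )


# -- fold-change filter -------------------------------------------------------


def fold_change_filter(X_mom, y, delta: float = 0.10) -> np.ndarray:
    """Boolean mask of proteins whose mean linear MoM differs >= ``delta``.

    The criterion is ``|mean(MoM_cases) / mean(MoM_controls) - 1| >= delta``
    with arithmetic means on the linear MoM scale, boundary inclusive.
    """
    X = np.asarray(X_mom, float)
    y = np.asarray(y, int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValidationError("fold-change filter requires both groups")
    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m1 / m0
    return np.abs(ratio - 1.0) >= delta - 1e-12  # boundary-inclusive despite round-off


# -- panel selection ----------------------------------------------------------


@dataclass
class MarkerPanel:
    """Selected panel with its discriminant and the selection trace."""

    proteins: list[str]
    coef: pd.Series
    intercept: float
    trace: pd.DataFrame  # columns: size, added, pauc, gain, accepted
    ranking: pd.DataFrame  # columns: protein, pauc, auc (descending rank order)
    status: str  # "ok" | "empty"
    pauc_scale: str = "raw"

    def to_json(self) -> str:
        return json.dumps(
            {
                "proteins": self.proteins,
                "coef": self.coef.to_dict(),
                "intercept": self.intercept,
                "trace": self.trace.to_dict(orient="records"),
                "ranking": self.ranking.to_dict(orient="records"),
                "status": self.status,
                "pauc_scale": self.pauc_scale,
            }
        )


class PanelSelector(BaseEstimator):
    """Parsimonious LDA marker panel chosen by pAUC-ranked forward inclusion.

    Fitting (on linear MoM features unless ``log2_input``) performs the full
    selection pipeline: 10%-change filter, single-marker LOOCV pAUC ranking,
    nested candidate panels of increasing size along the ranking, and the
    +0.01 pAUC acceptance rule, stopping at the first rejected size.  The
    final discriminant is refitted on all patients with the accepted set.

    Parameters
    ----------
    k_max: maximum panel size (5 in the reference analysis).
    gain: minimum pAUC improvement required to accept a larger panel.
    delta: group-mean MoM change required to keep a protein (0.10 = 10%).
    fpr_cap: FPR range of the partial AUC used for ranking and acceptance.
    fpr_target: FPR at which sensitivity is later reported.
    pauc_scale: "raw" integrates TPR over [0, fpr_cap]; "normalized"
        divides by ``fpr_cap`` (McClish) before applying ``gain``.
    log2_input: set True when ``X`` already holds log2 MoM values.
    ridge: relative ridge added to the pooled covariance.

    Attributes
    ----------
    panel_: ordered list of selected proteins (possibly empty).
    coef_, intercept_: final discriminant on the log2 MoM scale.
    trace_: per-size pAUC record with acceptance decisions.
    ranking_: single-marker pAUC/AUC ranking of filter survivors.
    status_: "ok" or "empty" (nothing survived the filter).
    """

    def __init__(self, k_max: int = 5, gain: float = 0.01, delta: float = 0.10,
                 fpr_cap: float = 0.5, fpr_target: float = 0.10,
                 pauc_scale: str = "raw", log2_input: bool = False,
                 ridge: float = _RIDGE):
        self.k_max = k_max
        self.gain = gain
        self.delta = delta
        self.fpr_cap = fpr_cap
        self.fpr_target = fpr_target
        self.pauc_scale = pauc_scale
        self.log2_input = log2_input
        self.ridge = ridge

    def _scaled(self, pauc: float) -> float:
        return pauc / self.fpr_cap if self.pauc_scale == "normalized" else pauc

    def fit(self, X, y) -> "PanelSelector":
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [
            f"p{i}" for i in range(np.shape(X)[1])
        ]
        Xv = np.asarray(X, float)
        y = np.asarray(y, int)
        X_lin = np.exp2(Xv) if self.log2_input else Xv
        X_log = Xv if self.log2_input else np.log2(Xv)
        self.feature_names_in_ = np.asarray(names, dtype=object)

        keep = fold_change_filter(X_lin, y, self.delta)
        self.n_filtered_ = int(len(names) - keep.sum())
        if not keep.any():
            self.panel_ = []
            self.coef_ = pd.Series(dtype=float)
            self.intercept_ = 0.0
            self.ranking_ = pd.DataFrame(columns=["protein", "pauc", "auc"])
            self.trace_ = pd.DataFrame(columns=["size", "added", "pauc", "gain", "accepted"])
            self.status_ = "empty"
            return self

        surv_idx = np.flatnonzero(keep)
        surv_names = [names[j] for j in surv_idx]
        scores = _loocv_scores_single_all(X_log[:, surv_idx], y, self.ridge)
        stats = [roc_metrics(scores[:, j], y, self.fpr_cap, self.fpr_target)
                 for j in range(len(surv_idx))]
        ranking = pd.DataFrame(
            {
                "protein": surv_names,
                "pauc": [self._scaled(s.pauc) for s in stats],
                "auc": [s.auc for s in stats],
            }
        ).sort_values(["pauc", "auc", "protein"], ascending=[False, False, True],
                      kind="mergesort").reset_index(drop=True)
        self.ranking_ = ranking

        ordered = ranking["protein"].tolist()
        name_to_col = {nm: names.index(nm) for nm in ordered}
        rows = []
        best_pauc = -np.inf
        accepted: list[str] = []
        for k in range(1, min(self.k_max, len(ordered)) + 1):
            cand = ordered[:k]
            cols = [name_to_col[nm] for nm in cand]
            cv = loocv_scores(X_log[:, cols], y, self.ridge)
            pauc_k = self._scaled(roc_metrics(cv, y, self.fpr_cap, self.fpr_target).pauc)
            gain_k = pauc_k - best_pauc if k > 1 else np.nan
            ok = k == 1 or gain_k >= self.gain
            rows.append(
                {"size": k, "added": cand[-1], "pauc": pauc_k, "gain": gain_k, "accepted": ok}
            )
            if not ok:
                break
            accepted = cand
            best_pauc = pauc_k

        cols = [name_to_col[nm] for nm in accepted]
        w, offset = _lda_fit(X_log[:, cols], y, self.ridge)
        self.panel_ = accepted
        self.coef_ = pd.Series(w, index=accepted)
        self.intercept_ = -offset
        self.trace_ = pd.DataFrame(rows)
        self.status_ = "ok"
        return self

    def decision_function(self, X) -> np.ndarray:
        """Discriminant score (log2 MoM scale) of new patients."""
        if not hasattr(self, "status_"):
            raise ValidationError("PanelSelector must be fitted first")
        if self.status_ == "empty" or not self.panel_:
            return np.zeros(np.shape(X)[0])
        if isinstance(X, pd.DataFrame):
            Xv = X[self.panel_].to_numpy(float)
        else:
            names = list(self.feature_names_in_)
            Xv = np.asarray(X, float)[:, [names.index(nm) for nm in self.panel_]]
        X_log = Xv if self.log2_input else np.log2(Xv)
        return X_log @ self.coef_.to_numpy() + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def build_panel(view: IntervalView, k_max: int = 5, gain: float = 0.01,
                delta: float = 0.10, fpr_cap: float = 0.5,
                pauc_scale: str = "raw") -> MarkerPanel:
    """Run the selection pipeline on an interval view (linear MoM features)."""
    sel = PanelSelector(k_max=k_max, gain=gain, delta=delta, fpr_cap=fpr_cap,
                        pauc_scale=pauc_scale)
    sel.fit(view.X, view.y)
    return MarkerPanel(
        proteins=sel.panel_,
        coef=sel.coef_,
        intercept=sel.intercept_,
        trace=sel.trace_,
        ranking=sel.ranking_,
        status=sel.status_,
        pauc_scale=pauc_scale,
    )
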