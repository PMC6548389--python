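"""Outer-loop performance estimation around the whole selection pipeline.

Because the marker panel is itself chosen from the data, naive resubstitution
performance would be optimistic.  Both schemes here rerun the complete
pipeline (fold-change filter, pAUC ranking, panel acceptance, final LDA fit)
inside every training resample and measure performance only on patients the
training step never saw:

* stratified bootstrap — resample cases and controls with replacement to the
  original class sizes; out-of-bag patients form the test set;
* repeated stratified 3-fold cross-validation — 67 repeats yielding 201
  train/test pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import IntervalView
from .errors import ValidationError
from .markers import PanelSelector, roc_metrics

_METRICS = ("auc", "pauc", "sensitivity", "specificity")


@dataclass
class ResampleReport:
    """Per-iteration out-of-sample metrics plus panel inclusion bookkeeping."""

    scheme: str
    n_iterations: int
    iterations: pd.DataFrame  # auc, pauc, sensitivity, specificity, panel, panel_size, ...
    inclusion: pd.Series  # per-protein fraction of iterations in the accepted panel
    aggregates: dict
    seed: int
    params: dict
    n_redraws: int = 0

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "metric": m,
                "mean": self.aggregates[m]["mean"],
                "ci_lo": self.aggregates[m]["ci_lo"],
                "ci_hi": self.aggregates[m]["ci_hi"],
            }
            for m in _METRICS
        ]
        return pd.DataFrame(rows)


def _evaluate_split(view: IntervalView, train_idx, test_idx, selector_params,
                    fpr_cap, fpr_target):
    sel = PanelSelector(fpr_cap=fpr_cap, fpr_target=fpr_target, **selector_params)
    sel.fit(view.X.iloc[train_idx], view.y[train_idx])
    scores = sel.decision_function(view.X.iloc[test_idx])
    m = roc_metrics(scores, view.y[test_idx], fpr_cap=fpr_cap, fpr_target=fpr_target)
    return sel, m


def _aggregate(records: list[dict], proteins, n_iter: int):
    iters = pd.DataFrame(records)
    agg = {
        m: {
            "mean": float(iters[m].mean()),
            "ci_lo": float(np.percentile(iters[m], 2.5)),
            "ci_hi": float(np.percentile(iters[m], 97.5)),
        }
        for m in _METRICS
    }
    counts = pd.Series(0, index=list(proteins), dtype=float)
    for panel in iters["panel"]:
        for prot in panel:
            counts[prot] += 1
    return iters, counts / n_iter, agg


def bootstrap_evaluate(view: IntervalView, B: int = 200, seed: int = 0,
                       fpr_cap: float = 0.5, fpr_target: float = 0.10,
                       **selector_params) -> ResampleReport:
    """Stratified bootstrap of the full selection pipeline.

    Each iteration draws cases and controls separately with replacement to
    the original class sizes, refits the entire pipeline on the resample,
    and scores the out-of-bag patients.  Iterations whose out-of-bag set
    lacks a class are redrawn (and counted), keeping ``B`` fixed.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    y = view.y
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if min(len(cases), len(controls)) < 5:
        raise ValidationError("bootstrap evaluation needs >= 5 patients per class")

    # one independent substream per iteration: iteration i reproducible alone
    streams = np.random.SeedSequence(seed).spawn(B)
    records = []
    n_redraws = 0
    for i in range(B):
        rng = np.random.default_rng(streams[i])
        while True:
            train = np.r_[rng.choice(cases, size=len(cases), replace=True),
                          rng.choice(controls, size=len(controls), replace=True)]
            oob = np.setdiff1d(np.arange(len(y)), train)
            if len(oob) and 0 < y[oob].sum() < len(oob):
                break
            n_redraws += 1
        sel, m = _evaluate_split(view, train, oob, selector_params, fpr_cap, fpr_target)
        records.append(
            {
                "iteration": i,
                "auc": m.auc,
                "pauc": m.pauc,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "panel": tuple(sel.panel_),
                "panel_size": len(sel.panel_),
                "n_test_cases": int(y[oob].sum()),
                "n_test_controls": int(len(oob) - y[oob].sum()),
            }
        )
    iters, inclusion, agg = _aggregate(records, view.X.columns, B)
    return ResampleReport(
        scheme="bootstrap", n_iterations=B, iterations=iters, inclusion=inclusion,
        aggregates=agg, seed=seed, n_redraws=n_redraws,
        params={"fpr_cap": fpr_cap, "fpr_target": fpr_target, **selector_params},
    )


def repeated_cv_evaluate(view: IntervalView, repeats: int = 67, folds: int = 3,
                         seed: int = 0, fpr_cap: float = 0.5,
                         fpr_target: float = 0.10, **selector_params) -> ResampleReport:
    """Repeated stratified k-fold CV of the full pipeline (67 x 3 = 201 pairs).

    Folds are stratified by class with sizes differing by at most one patient
    per class (round-robin remainder assignment).
    """
    if repeats < 1 or folds < 2:
        raise ValidationError("repeats must be >= 1 and folds >= 2")
    y = view.y
    cases = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if min(len(cases), len(controls)) < folds:
        raise ValidationError(f"each class needs at least {folds} patients for {folds}-fold CV")

    streams = np.random.SeedSequence(seed).spawn(repeats)
    records = []
    it = 0
    for r in range(repeats):
        rng = np.random.default_rng(streams[r])
        fold_of = np.empty(len(y), dtype=int)
        for cls_idx in (cases, controls):
            perm = rng.permutation(cls_idx)
            fold_of[perm] = np.arange(len(perm)) % folds
        for f in range(folds):
            test = np.flatnonzero(fold_of == f)
            train = np.flatnonzero(fold_of != f)
            sel, m = _evaluate_split(view, train, test, selector_params, fpr_cap, fpr_target)
            records.append(
                {
                    "iteration": it,
                    "repeat": r,
                    "fold": f,
                    "auc": m.auc,
                    "pauc": m.pauc,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "panel": tuple(sel.panel_),
                    "panel_size": len(sel.panel_),
                    "n_test_cases": int(y[test].sum()),
                    "n_test_controls": int(len(test) - y[test].sum()),
                }
            )
            it += 1
    n_pairs = repeats * folds
    iters, inclusion, agg = _aggregate(records, view.X.columns, n_pairs)
    return ResampleReport(
        scheme="repeated_cv", n_iterations=n_pairs, iterations=iters,
        inclusion=inclusion, aggregates=agg, seed=seed,
        params={"repeats": repeats, "folds": folds, "fpr_cap": fpr_cap,
                "fpr_target": fpr_target, **selector_params},
    )


def inclusion_frequencies(report: ResampleReport, min_pct: float = 10.0):
    """Proteins selected in at least ``min_pct`` percent of iterations.

    Returns ``(protein, percent)`` pairs sorted by descending percentage,
    boundary inclusive (20 of 200 iterations = 10% is listed).
    """
    pct = report.inclusion * 100.0
    kept = pct[pct >= min_pct].sort_values(ascending=False)
    return list(kept.items())
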