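import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gaussian_mom_view, make_view
from ppx import build_panel, fold_change_filter, loocv_scores, roc_metrics
from ppx.errors import ValidationError
from ppx.markers import PanelSelector, _loocv_scores_single_all


def oracle_loocv(X, y, ridge=1e-8):
    """Plain refit-per-fold LDA oracle, written from the definition."""
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, p = X.shape
    out = np.empty(n)
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        Xi, yi = X[keep], y[keep]
        mu0 = Xi[yi == 0].mean(axis=0)
        mu1 = Xi[yi == 1].mean(axis=0)
        S = np.zeros((p, p))
        for x, lab in zip(Xi, yi):
            d = x - (mu1 if lab else mu0)
            S += np.outer(d, d)
        S /= len(yi) - 2
        tr = np.trace(S)
        S += (ridge * tr / p if tr > 0 else ridge) * np.eye(p)
        w = np.linalg.solve(S, mu1 - mu0)
        out[i] = w @ X[i] - w @ (mu0 + mu1) / 2
    return out


def oracle_auc_pairs(scores, y):
    """Mann-Whitney AUC by exhaustive pair enumeration (ties count half)."""
    cases = scores[y == 1]
    ctrls = scores[y == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in ctrls)
    return wins / (len(cases) * len(ctrls))


def oracle_pauc_enumeration(scores, y, cap):
    """Partial AUC from the all-threshold ROC polygon, one segment at a time."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    area = 0.0
    for (f0, t0), (f1, t1) in zip(zip(fpr, tpr), zip(fpr[1:], tpr[1:])):
        if f1 <= cap:
            area += (f1 - f0) * (t0 + t1) / 2
        elif f0 < cap:
            t_cap = t0 + (t1 - t0) * (cap - f0) / (f1 - f0)
            area += (cap - f0) * (t0 + t_cap) / 2
    return area


class TestLoocvScores:
    def test_matches_refit_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 3))
        y = np.r_[np.ones(12, int), np.zeros(18, int)]
        X[y == 1] += 0.8
        assert np.max(np.abs(loocv_scores(X, y) - oracle_loocv(X, y))) < 1e-10

    def test_single_feature_fast_path_matches_oracle(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(40, 7))
        y = rng.integers(0, 2, 40)
        y[:3], y[-3:] = 1, 0
        fast = _loocv_scores_single_all(X, y)
        for j in range(7):
            assert np.max(np.abs(fast[:, j] - oracle_loocv(X[:, [j]], y))) < 1e-10

    def test_perfectly_separated_feature_gives_auc_one(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        X = np.r_[np.linspace(10, 11, 5), np.linspace(0, 1, 5)].reshape(-1, 1)
        scores = loocv_scores(X, y)
        assert roc_metrics(scores, y).auc == 1.0

    def test_constant_feature_is_inert(self):
        rng = np.random.default_rng(23)
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        info = rng.normal(size=30) + y * 1.5
        X2 = np.c_[info, np.full(30, 3.14)]
        s_both = loocv_scores(X2, y)
        s_alone = loocv_scores(info.reshape(-1, 1), y)
        assert np.corrcoef(s_both, s_alone)[0, 1] > 1 - 1e-6
        assert roc_metrics(s_both, y).auc == pytest.approx(
            roc_metrics(s_alone, y).auc, abs=1e-12
        )

    def test_requires_two_per_class(self):
        with pytest.raises(ValidationError):
            loocv_scores(np.zeros((3, 1)), np.array([1, 0, 0]))


class TestRocMetrics:
    def test_worked_example(self):
        # cases {3, 1}, controls {2, 0}: ROC (0,0)->(0,.5)->(.5,.5)->(.5,1)->(1,1)
        scores = np.array([3.0, 1.0, 2.0, 0.0])
        y = np.array([1, 1, 0, 0])
        m = roc_metrics(scores, y, fpr_cap=0.5, fpr_target=0.10)
        assert m.auc == pytest.approx(0.75)
        assert m.pauc == pytest.approx(0.25)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == 1.0

    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        m = roc_metrics(np.array([5.0, 4.0, 1.0, 0.0]), y)
        assert (m.auc, m.pauc, m.sensitivity) == (1.0, 0.5, 1.0)

    def test_all_ties_give_chance(self):
        y = np.array([1, 1, 0, 0, 0])
        m = roc_metrics(np.ones(5), y)
        assert m.auc == pytest.approx(0.5)
        assert m.pauc == pytest.approx(0.125)  # area under the diagonal to 0.5
        assert m.sensitivity == 0.0

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_metrics(np.arange(4.0), np.ones(4, int))

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=12),
        st.data(),
    )
    def test_matches_enumeration_oracles_with_ties(self, raw, data):
        scores = np.asarray(raw, float)
        n = len(scores)
        y = np.asarray(
            data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)), int
        )
        if y.sum() in (0, n):
            y[0], y[-1] = 1, 0
        m = roc_metrics(scores, y)
        assert m.auc == pytest.approx(oracle_auc_pairs(scores, y), abs=1e-12)
        assert m.pauc == pytest.approx(oracle_pauc_enumeration(scores, y, 0.5), abs=1e-12)
        assert m.pauc <= min(m.auc, 0.5) + 1e-12
        assert m.specificity >= 0.9

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        y = rng.integers(0, 2, 20)
        y[0], y[1] = 1, 0
        m1 = roc_metrics(scores, y)
        m2 = roc_metrics(np.exp(3 * scores) + 7, y)
        assert (m1.auc, m1.pauc, m1.sensitivity) == pytest.approx(
            (m2.auc, m2.pauc, m2.sensitivity)
        )

    def test_pauc_complement_consistency(self):
        # area below cap + area above cap = AUC on the same polygon
        rng = np.random.default_rng(24)
        for _ in range(20):
            scores = rng.integers(0, 4, 10).astype(float)
            y = rng.integers(0, 2, 10)
            y[0], y[1] = 1, 0
            m = roc_metrics(scores, y)
            upper = oracle_pauc_enumeration(scores, y, 1.0) - oracle_pauc_enumeration(
                scores, y, 0.5
            )
            assert m.auc == pytest.approx(m.pauc + upper, abs=1e-12)


class TestFoldChangeFilter:
    def test_boundary_inclusive(self):
        X = np.c_[np.r_[np.full(5, 1.10), np.full(5, 1.00)]]
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert fold_change_filter(X, y, delta=0.10)[0]

    def test_eight_percent_change_dropped(self):
        X = np.c_[np.r_[np.full(5, 0.92), np.full(5, 1.00)]]
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert not fold_change_filter(X, y, delta=0.10)[0]

    def test_identical_means_dropped(self):
        X = np.ones((10, 3))
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert not fold_change_filter(X, y).any()


class TestPanelSelection:
    def test_single_planted_marker_recovered(self):
        # 1 shifted marker among 99 nulls; selection should find it nearly always
        hits = 0
        n_rep = 100
        root = np.random.SeedSequence(77)
        for child in root.spawn(n_rep):
            rng = np.random.default_rng(child)
            view = gaussian_mom_view(rng, shifts={0: 1.5}, n_proteins=100)
            panel = build_panel(view)
            hits += panel.proteins[:1] == ["P0001"]
        assert hits >= 95

    def test_complementary_pair_selected(self):
        # second marker roughly doubles the discriminant information, so the
        # +0.01 pAUC rule admits it
        rng = np.random.default_rng(30)
        view = gaussian_mom_view(
            rng, n_cases=60, n_controls=120, n_proteins=30,
            shifts={0: 1.0, 1: 1.0}, sd=0.5,
        )
        panel = build_panel(view)
        assert set(panel.proteins[:2]) == {"P0001", "P0002"}
        assert len(panel.proteins) >= 2

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(31)
        view = gaussian_mom_view(rng, shifts={3: 1.2})
        p1 = build_panel(view)
        p2 = build_panel(view)
        assert p1.proteins == p2.proteins
        pd.testing.assert_frame_equal(p1.trace, p2.trace)

    def test_trace_obeys_gain_rule(self):
        rng = np.random.default_rng(32)
        view = gaussian_mom_view(rng, shifts={0: 0.8, 1: 0.8, 2: 0.8})
        panel = build_panel(view)
        accepted = panel.trace[panel.trace.accepted]
        paucs = accepted.pauc.to_numpy()
        assert np.all(np.diff(paucs) >= 0.01 - 1e-12)
        assert len(panel.proteins) <= 5
        rejected = panel.trace[~panel.trace.accepted]
        assert len(rejected) <= 1  # stops at the first rejection

    def test_nothing_survives_filter_gives_empty_status(self):
        X = np.ones((20, 4))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        sel = PanelSelector().fit(pd.DataFrame(X, columns=list("abcd")), y)
        assert sel.status_ == "empty"
        assert sel.panel_ == []
        assert np.all(sel.decision_function(pd.DataFrame(X, columns=list("abcd"))) == 0)

    def test_ranking_tiebreak_is_lexicographic(self):
        rng = np.random.default_rng(33)
        base = rng.normal(0, 0.5, size=40)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        base[y == 1] += 1.0
        X = np.exp2(np.c_[base, base])  # identical columns: tie on pAUC and AUC
        view = make_view(X, y)
        panel = build_panel(view)
        assert panel.ranking.protein.tolist()[:2] == ["P0001", "P0002"]

    def test_decision_function_orders_new_patients(self):
        rng = np.random.default_rng(34)
        view = gaussian_mom_view(rng, shifts={0: 2.0}, n_proteins=10)
        sel = PanelSelector().fit(view.X, view.y)
        new = pd.DataFrame(
            np.exp2(np.array([[2.0] + [0.0] * 9, [-2.0] + [0.0] * 9])),
            columns=view.X.columns,
        )
        lo, hi = sel.decision_function(new[::-1]), sel.decision_function(new)
        assert hi[0] > hi[1] and lo[0] < lo[1]
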