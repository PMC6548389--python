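import numpy as np
import pandas as pd
import pytest

from ppx import MoMReference, SynthConfig, define_contrast, generate_cohort
from ppx.cohort import IntervalView


def make_view(X, y, interval="8-16", contrast="all_early_pe") -> IntervalView:
    """Wrap a feature matrix and labels as an interval view for unit tests."""
    X = pd.DataFrame(np.asarray(X, float))
    X.columns = [f"P{i + 1:04d}" for i in range(X.shape[1])]
    y = np.asarray(y, int)
    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(y))],
            "label": np.where(y == 1, "case", "control"),
            "ga_weeks": np.full(len(y), 12.0),
        }
    )
    return IntervalView(interval=interval, contrast=contrast, patients=patients, X=X, y=y)


def gaussian_mom_view(rng, n_cases=33, n_controls=90, n_proteins=100,
                      shifts=None, sd=0.5) -> IntervalView:
    """Linear-MoM interval view drawn from the two-Gaussian log2 MoM model."""
    n = n_cases + n_controls
    y = np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)]
    log2mom = rng.normal(0.0, sd, size=(n, n_proteins))
    if shifts:
        for col, shift in shifts.items():
            log2mom[y == 1, col] += shift
    return make_view(np.exp2(log2mom), y)


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truth = generate_cohort(SynthConfig(), seed=0)
    return cohort, truth


@pytest.fixture(scope="session")
def default_mom(default_cohort):
    cohort, truth = default_cohort
    est = MoMReference().fit(cohort)
    mom = est.transform(cohort)
    labeled = define_contrast(mom, "all_early_pe")
    return labeled, truth, est
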