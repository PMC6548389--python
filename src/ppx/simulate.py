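"""Synthetic longitudinal case-control proteomic cohorts with known truth.

The generator emulates the structure the analysis assumes: enrolment in the
late first trimester, prenatal visits every ~4 weeks until delivery with
only a 2-6 sample subset retained per patient, early-onset case diagnoses
between 24.6 and 33.4 weeks (cases deliver shortly after diagnosis),
per-protein smooth gestational-age baseline curves on the log2 scale,
per-subject random intercepts, and interval-localized log2 MoM effect shifts
planted on a small marker subset.  Case subgroups (placental-lesion and
severe phenotypes) can carry larger effects via multipliers.

Ground truth (planted markers, variance components, closed-form single- and
multi-marker AUC) is returned alongside the cohort so downstream estimates
have an oracle to be checked against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CohortTable
from .errors import ConfigurationError


@dataclass(frozen=True)
class PlantedMarker:
    """A protein carrying an interval-localized case effect on the log2 MoM scale.

    The shift is active for gestational ages in ``[onset_ga, offset_ga)``;
    with ``ramp_weeks > 0`` it grows linearly over that many weeks from the
    onset instead of switching on abruptly, mimicking trajectories that
    diverge progressively.  The default ``offset_ga`` of infinity keeps the
    effect on for the rest of gestation.
    """

    protein: str
    shift: float
    onset_ga: float = 0.0
    offset_ga: float = float("inf")
    ramp_weeks: float = 0.0

    def effect_at(self, ga: np.ndarray) -> np.ndarray:
        ga = np.asarray(ga, float)
        window = (ga >= self.onset_ga) & (ga < self.offset_ga)
        if self.ramp_weeks <= 0:
            return self.shift * window
        ramp = np.clip((ga - self.onset_ga) / self.ramp_weeks, 0.0, 1.0)
        return self.shift * ramp * window


def _default_markers() -> tuple[PlantedMarker, ...]:
    # one dominant marker per analysis interval, magnitudes escalating toward
    # diagnosis and one down-regulated -- mirroring the interval-specific
    # marker sets and late-diverging trajectories of real early-onset disease
    return (
        PlantedMarker("P0001", 1.0, onset_ga=0.0, offset_ga=16.0),
        PlantedMarker("P0002", 1.4, onset_ga=16.0, offset_ga=22.0),
        PlantedMarker("P0003", -1.4, onset_ga=22.0, offset_ga=28.0),
        PlantedMarker("P0004", 2.0, onset_ga=28.0, offset_ga=32.0),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generator settings; defaults encode the emulated study design."""

    n_cases: int = 33
    n_controls: int = 90
    n_late_pe: int = 0
    n_proteins: int = 200
    # visit process
    enrol_ga: tuple[float, float] = (8.0, 12.0)
    visit_interval: float = 4.0
    visit_jitter: float = 0.5
    # prenatal visits densify late in gestation (standard schedule: every
    # 4 weeks to ~28 weeks, every 2 weeks thereafter)
    late_visit_interval: float = 2.0
    late_visit_from_ga: float = 28.0
    min_samples: int = 2
    max_samples: int = 6
    post_diagnosis_sample_p: float = 0.5
    # outcome timing (weeks)
    diagnosis_ga: tuple[float, float] = (24.6, 33.4)
    late_diagnosis_ga: tuple[float, float] = (34.0, 38.0)
    control_delivery_ga: tuple[float, float] = (38.5, 41.0)
    delivery_delay: tuple[float, float] = (0.0, 0.6)
    # protein model (log2 scale)
    baseline_intercept: tuple[float, float] = (8.0, 12.0)
    baseline_slope_sd: float = 0.03
    baseline_smooth_amplitude: float = 0.5
    baseline_kind_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # constant/linear/smooth
    tau: float = 0.3
    sigma: float = 0.4
    markers: tuple[PlantedMarker, ...] = field(default_factory=_default_markers)
    # subgroups
    mvm_fraction: float = 24 / 33
    severe_fraction: float = 23 / 33
    mvm_multiplier: float = 1.0
    severe_multiplier: float = 1.0
    late_pe_effect_scale: float = 0.0
    # covariates
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    smoking_p: float = 0.2
    age_mean: float = 24.0
    age_sd: float = 4.0
    nulliparity_p: float = 0.35
    bmi_case_shift: float = 0.0  # BMI difference of cases (confounded preset)
    bmi_effect: float = 0.0  # log2 shift per BMI standard deviation, all proteins

    @property
    def protein_names(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_proteins)]

    def validate(self) -> None:
        if self.tau <= 0 or self.sigma <= 0:
            raise ConfigurationError("tau and sigma must be positive")
        if not (0 <= self.mvm_fraction <= 1 and 0 <= self.severe_fraction <= 1):
            raise ConfigurationError("subgroup fractions must lie in [0, 1]")
        if self.min_samples < 1 or self.max_samples < self.min_samples:
            raise ConfigurationError("sample-count range is invalid")
        names = set(self.protein_names)
        for m in self.markers:
            if m.protein not in names:
                raise ConfigurationError(f"planted marker {m.protein!r} is not on the panel")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


def oracle_auc(effect: float, tau: float, sigma: float) -> float:
    """Closed-form AUC of a single marker under the two-Gaussian model.

    One sample per patient means the between-patient score variance is
    ``tau^2 + sigma^2`` in each group, giving
    ``AUC = Phi(effect / sqrt(2 (tau^2 + sigma^2)))``.
    """
    if tau <= 0 or sigma <= 0:
        raise ConfigurationError("tau and sigma must be positive")
    return float(norm.cdf(effect / np.sqrt(2.0 * (tau**2 + sigma**2))))


def oracle_panel_auc(shifts, tau: float, sigma: float) -> float:
    """Closed-form AUC of the optimal discriminant over independent markers."""
    shifts = np.asarray(shifts, float)
    return oracle_auc(float(np.sqrt(np.sum(shifts**2))), tau, sigma)


def _visit_schedule(rng, enrol, delivery, cfg: SynthConfig) -> np.ndarray:
    visits = [enrol]
    while True:
        step = (
            cfg.late_visit_interval
            if visits[-1] >= cfg.late_visit_from_ga
            else cfg.visit_interval
        )
        nxt = visits[-1] + step + rng.uniform(-cfg.visit_jitter, cfg.visit_jitter)
        if nxt >= delivery:
            break
        visits.append(nxt)
    return np.asarray(visits)


def _retained(rng, schedule: np.ndarray, cfg: SynthConfig, diagnosis: float) -> np.ndarray:
    n_keep = int(rng.integers(cfg.min_samples, cfg.max_samples + 1))
    if len(schedule) <= n_keep:
        return schedule
    # the enrolment draw is always banked; for patients who develop disease,
    # so is the last visit before diagnosis (the admission-adjacent sample)
    forced = [0]
    if np.isfinite(diagnosis):
        pre = np.flatnonzero(schedule < diagnosis)
        if len(pre):
            forced.append(int(pre[-1]))
    forced = sorted(set(forced))
    pool = np.setdiff1d(np.arange(len(schedule)), forced)
    n_extra = max(n_keep - len(forced), 0)
    rest = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
    return schedule[np.sort(np.r_[forced, rest].astype(int))]


def generate_cohort(config: SynthConfig | None = None, seed: int = 0):
    """Generate a cohort and its ground-truth record.

    Returns ``(CohortTable, ground_truth)`` where the ground truth carries
    the planted markers, variance components, and closed-form oracle AUCs.
    Identical seeds give identical cohorts.
    """
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    proteins = cfg.protein_names
    marker_idx = {m.protein: proteins.index(m.protein) for m in cfg.markers}

    # per-protein baseline curves on the log2 scale
    kinds = rng.choice(3, size=cfg.n_proteins, p=cfg.baseline_kind_probs)
    intercepts = rng.uniform(*cfg.baseline_intercept, size=cfg.n_proteins)
    slopes = np.where(kinds >= 1, rng.normal(0.0, cfg.baseline_slope_sd, cfg.n_proteins), 0.0)
    amps = np.where(kinds == 2, cfg.baseline_smooth_amplitude, 0.0)
    phases = rng.uniform(0, 2 * np.pi, cfg.n_proteins)

    def baseline(ga: np.ndarray) -> np.ndarray:
        ga = ga[:, None]
        return intercepts + slopes * (ga - 20.0) + amps * np.sin(2 * np.pi * ga / 20.0 + phases)

    # patient roster with flags
    ids, early, mvm, severe, late = [], [], [], [], []
    n_mvm = int(round(cfg.mvm_fraction * cfg.n_cases))
    n_sev = int(round(cfg.severe_fraction * cfg.n_cases))
    mvm_set = set(rng.choice(cfg.n_cases, size=n_mvm, replace=False)) if cfg.n_cases else set()
    sev_set = set(rng.choice(cfg.n_cases, size=n_sev, replace=False)) if cfg.n_cases else set()
    for i in range(cfg.n_cases):
        ids.append(f"C{i + 1:03d}")
        early.append(1)
        mvm.append(int(i in mvm_set))
        severe.append(int(i in sev_set))
        late.append(0)
    for i in range(cfg.n_late_pe):
        ids.append(f"L{i + 1:03d}")
        early.append(0)
        mvm.append(0)
        severe.append(0)
        late.append(1)
    for i in range(cfg.n_controls):
        ids.append(f"N{i + 1:03d}")
        early.append(0)
        mvm.append(0)
        severe.append(0)
        late.append(0)

    rows = []
    log2_rows = []
    for j, pid in enumerate(ids):
        enrol = rng.uniform(*cfg.enrol_ga)
        if early[j]:
            diagnosis = rng.uniform(*cfg.diagnosis_ga)
            delivery = diagnosis + rng.uniform(*cfg.delivery_delay)
        elif late[j]:
            diagnosis = rng.uniform(*cfg.late_diagnosis_ga)
            delivery = diagnosis + rng.uniform(*cfg.delivery_delay)
        else:
            diagnosis = np.nan
            delivery = rng.uniform(*cfg.control_delivery_ga)
        ga = _retained(rng, _visit_schedule(rng, enrol, delivery, cfg), cfg, diagnosis)
        if np.isfinite(diagnosis) and rng.uniform() < cfg.post_diagnosis_sample_p:
            ga = np.r_[ga[ga < diagnosis], diagnosis]  # visit at the diagnosis admission

        b = rng.normal(0.0, cfg.tau, size=cfg.n_proteins)  # subject intercepts
        eps = rng.normal(0.0, cfg.sigma, size=(len(ga), cfg.n_proteins))
        log2_vals = baseline(ga) + b + eps
        if early[j] or (late[j] and cfg.late_pe_effect_scale != 0.0):
            scale = 1.0 if early[j] else cfg.late_pe_effect_scale
            if early[j]:
                if mvm[j]:
                    scale *= cfg.mvm_multiplier
                if severe[j]:
                    scale *= cfg.severe_multiplier
            for m in cfg.markers:
                log2_vals[:, marker_idx[m.protein]] += scale * m.effect_at(ga)
        for k, g in enumerate(ga):
            rows.append((pid, float(g), diagnosis, early[j], mvm[j], severe[j], late[j]))
            log2_rows.append(log2_vals[k])

    meta = pd.DataFrame(
        rows,
        columns=["ID", "GA", "GADiagnosis", "EarlyPE", "EarlyPE_MVM", "EarlyPE_Severe", "LatePE"],
    )
    if cfg.n_late_pe == 0:
        meta = meta.drop(columns="LatePE")
    abund = pd.DataFrame(np.exp2(np.asarray(log2_rows)), columns=proteins)

    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=len(ids)).clip(16, 55)
    bmi += cfg.bmi_case_shift * np.asarray(early, float)
    covariates = pd.DataFrame(
        {
            "ID": ids,
            "BMI": bmi,
            "Smoking": rng.binomial(1, cfg.smoking_p, size=len(ids)),
            "MaternalAge": rng.normal(cfg.age_mean, cfg.age_sd, size=len(ids)).clip(15, 48),
            "Nulliparity": rng.binomial(1, cfg.nulliparity_p, size=len(ids)),
        }
    ).set_index("ID")
    if cfg.bmi_effect != 0.0:
        z = (covariates["BMI"].to_numpy() - cfg.bmi_mean) / cfg.bmi_sd
        per_sample = meta["ID"].map(dict(zip(ids, z))).to_numpy()
        abund = abund.mul(np.exp2(cfg.bmi_effect * per_sample), axis=0)

    cohort = CohortTable(pd.concat([meta, abund], axis=1), covariates=covariates)
    total_var = cfg.tau**2 + cfg.sigma**2
    truth = {
        "seed": seed,
        "tau": cfg.tau,
        "sigma": cfg.sigma,
        "markers": [dataclasses.asdict(m) for m in cfg.markers],
        "oracle_auc": {m.protein: oracle_auc(abs(m.shift), cfg.tau, cfg.sigma)
                       for m in cfg.markers},
        "oracle_panel_auc": oracle_panel_auc([m.shift for m in cfg.markers], cfg.tau, cfg.sigma)
        if cfg.markers
        else 0.5,
        "total_variance": total_var,
        "config": dataclasses.asdict(cfg),
    }
    return cohort, truth
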