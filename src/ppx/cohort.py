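"""Cohort file I/O, gestational-age intervals, contrasts, and interval views.

The cohort layout is a long-format delimited table: one row per plasma
sample, metadata columns first (patient ID, gestational age at venipuncture,
GA at diagnosis, outcome flags), then one column per protein analyte.
Repeated samples from the same patient share an ID; controls have an empty
GA-at-diagnosis field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SchemaError, ValidationError

#: Canonical metadata headers, in file order (matches the deposited layout).
METADATA_COLUMNS = ["ID", "GA", "GADiagnosis", "EarlyPE", "EarlyPE_MVM", "EarlyPE_Severe"]
#: Optional extra flag enabling the combined early-vs-(control + late PE) contrast.
LATE_PE_COLUMN = "LatePE"

COVARIATE_COLUMNS = ["ID", "BMI", "Smoking", "MaternalAge", "Nulliparity"]

CONTRAST_MODES = ("all_early_pe", "mvm_only", "severe_only", "early_vs_control_plus_late")


@dataclass(frozen=True)
class GAIntervalScheme:
    """Ordered, non-overlapping gestational-age intervals in weeks.

    Membership is half-open on the left: interval *i* covers
    ``(upper_{i-1}, upper_i]`` with the first interval closed at its lower
    bound.  GA values falling in the typographic gaps of printed bounds
    (e.g. 16.05 between "8-16" and "16.1-22") therefore join the upper
    interval, treating the printed ".1" bounds as display precision of a
    continuous variable.
    """

    intervals: tuple[tuple[str, float, float], ...] = (
        ("8-16", 8.0, 16.0),
        ("16.1-22", 16.1, 22.0),
        ("22.1-28", 22.1, 28.0),
        ("28.1-32", 28.1, 32.0),
        ("32.1-36", 32.1, 36.0),
    )

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for label, lo, hi in self.intervals:
            if not (0 < lo < hi):
                raise ValidationError(f"interval {label!r}: bounds must be positive and increasing")
            if lo < prev_hi:
                raise ValidationError(f"interval {label!r} overlaps its predecessor")
            prev_hi = hi

    @property
    def labels(self) -> list[str]:
        return [label for label, _, _ in self.intervals]

    def bounds(self, label: str) -> tuple[float, float]:
        for lab, lo, hi in self.intervals:
            if lab == label:
                return lo, hi
        raise KeyError(f"unknown gestational-age interval {label!r}")

    def midpoint(self, label: str) -> float:
        lo, hi = self.bounds(label)
        return 0.5 * (lo + hi)

    def assign(self, ga_weeks: float) -> str | None:
        """Label of the interval containing ``ga_weeks``, or ``None``."""
        if not np.isfinite(ga_weeks) or ga_weeks <= 0:
            raise ValidationError(f"gestational age must be positive, got {ga_weeks!r}")
        first_lo = self.intervals[0][1]
        if ga_weeks < first_lo:
            return None
        lower = first_lo  # first interval closed at its lower bound
        for i, (label, _lo, hi) in enumerate(self.intervals):
            inside = (ga_weeks >= lower) if i == 0 else (ga_weeks > lower)
            if inside and ga_weeks <= hi:
                return label
            lower = hi
        return None


DEFAULT_SCHEME = GAIntervalScheme()


def assign_interval(ga_weeks: float, scheme: GAIntervalScheme = DEFAULT_SCHEME) -> str | None:
    """Assign a gestational age (weeks) to its interval label (or ``None``)."""
    return scheme.assign(ga_weeks)


class CohortTable:
    """Validated long-format repeated-measures cohort.

    Parameters
    ----------
    data:
        One row per sample; metadata columns (:data:`METADATA_COLUMNS`,
        optionally ``LatePE``) followed by one numeric column per protein.
    covariates:
        Optional per-patient table indexed by ``ID`` with columns BMI,
        Smoking, MaternalAge, Nulliparity.
    labels:
        Optional per-patient case/control/excluded assignment produced by
        :func:`define_contrast`; carried with its contrast-mode provenance.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: pd.DataFrame | None = None,
        labels: pd.Series | None = None,
        contrast: str | None = None,
        validate: bool = True,
    ) -> None:
        self.data = data.reset_index(drop=True)
        self.covariates = covariates
        self.labels = labels
        self.contrast = contrast
        meta = set(METADATA_COLUMNS) | {LATE_PE_COLUMN}
        self.proteins = [c for c in self.data.columns if c not in meta]
        if validate:
            self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required metadata column {col!r}")
        if not self.proteins:
            raise SchemaError("no protein columns found after the metadata columns")
        if df.duplicated(subset=["ID", "GA"]).any():
            dup = df.loc[df.duplicated(subset=["ID", "GA"]), ["ID", "GA"]].iloc[0]
            raise ValidationError(
                f"duplicate sample for patient {dup['ID']!r} at GA {dup['GA']} weeks"
            )
        ga = pd.to_numeric(df["GA"], errors="coerce")
        if ga.isna().any() or (ga <= 0).any():
            raise ValidationError("GA must be a positive number for every sample")
        for col in self.proteins:
            vals = df[col]
            if not pd.api.types.is_numeric_dtype(vals):
                bad = vals[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
                row = bad.index[0] if len(bad) else vals.index[vals.isna()][0]
                raise ParseError(
                    f"non-numeric abundance in column {col!r}, row {row}: {vals.iloc[0]!r}"
                )
            if (vals < 0).any():
                row = vals.index[vals < 0][0]
                raise ValidationError(f"negative abundance in column {col!r}, row {row}")
        flags = ["EarlyPE", "EarlyPE_MVM", "EarlyPE_Severe"]
        if LATE_PE_COLUMN in df.columns:
            flags = flags + [LATE_PE_COLUMN]
        for col in flags:
            if not df[col].isin([0, 1]).all():
                raise ValidationError(f"flag column {col!r} must be binary 0/1")
        if (df["EarlyPE_MVM"] > df["EarlyPE"]).any():
            raise ValidationError("EarlyPE_MVM = 1 requires EarlyPE = 1")
        if (df["EarlyPE_Severe"] > df["EarlyPE"]).any():
            raise ValidationError("EarlyPE_Severe = 1 requires EarlyPE = 1")
        diagnosed = df["GADiagnosis"].notna()
        is_pe = df["EarlyPE"] == 1
        if LATE_PE_COLUMN in df.columns:
            is_pe = is_pe | (df[LATE_PE_COLUMN] == 1)
        if (diagnosed & ~is_pe).any():
            raise ValidationError("GADiagnosis present for a patient without a PE flag")
        per_patient = df.groupby("ID")[flags + ["GADiagnosis"]].nunique(dropna=False)
        if (per_patient > 1).any().any():
            raise ValidationError("group flags and GADiagnosis must be constant within a patient")

    # -- accessors ----------------------------------------------------------

    @property
    def patients(self) -> pd.DataFrame:
        """One row per patient with the patient-level metadata."""
        cols = [c for c in self.data.columns if c in set(METADATA_COLUMNS) | {LATE_PE_COLUMN}]
        cols.remove("GA")
        return self.data[cols].drop_duplicates("ID").set_index("ID")

    @property
    def has_late_pe(self) -> bool:
        return LATE_PE_COLUMN in self.data.columns and (self.data[LATE_PE_COLUMN] == 1).any()

    def group_counts(self) -> dict[str, int]:
        pats = self.patients
        counts = {
            "patients": len(pats),
            "early_pe": int((pats["EarlyPE"] == 1).sum()),
            "early_pe_mvm": int((pats["EarlyPE_MVM"] == 1).sum()),
            "early_pe_severe": int((pats["EarlyPE_Severe"] == 1).sum()),
        }
        if LATE_PE_COLUMN in pats.columns:
            counts["late_pe"] = int((pats[LATE_PE_COLUMN] == 1).sum())
            counts["controls"] = int(
                ((pats["EarlyPE"] == 0) & (pats[LATE_PE_COLUMN] == 0)).sum()
            )
        else:
            counts["controls"] = int((pats["EarlyPE"] == 0).sum())
        return counts

    def prediagnosis_sample_counts(self) -> pd.Series:
        """Number of strictly pre-diagnosis samples per patient.

        Controls (no diagnosis GA) contribute all of their samples.
        """
        df = self.data
        keep = df["GADiagnosis"].isna() | (df["GA"] < df["GADiagnosis"])
        counts = df.loc[keep].groupby("ID").size()
        return counts.reindex(self.patients.index, fill_value=0)

    def with_labels(self, labels: pd.Series, contrast: str) -> "CohortTable":
        return CohortTable(
            self.data, covariates=self.covariates, labels=labels, contrast=contrast,
            validate=False,
        )

    def with_abundances(self, values: pd.DataFrame) -> "CohortTable":
        """Return a copy whose protein columns are replaced by ``values``."""
        if list(values.columns) != self.proteins or len(values) != len(self.data):
            raise ValidationError("replacement abundances must match the cohort layout")
        out = self.data.copy()
        out[self.proteins] = values.to_numpy()
        return CohortTable(
            out, covariates=self.covariates, labels=self.labels, contrast=self.contrast,
            validate=False,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        c = self.group_counts()
        return (
            f"CohortTable({c['patients']} patients, {len(self.data)} samples, "
            f"{len(self.proteins)} proteins, contrast={self.contrast!r})"
        )


@dataclass
class IntervalView:
    """One selected pre-diagnosis sample per patient inside one GA interval.

    ``X`` holds the per-patient feature vectors (typically linear MoM);
    ``y`` is 1 for cases and 0 for controls, aligned with ``patients``.
    """

    interval: str
    contrast: str
    patients: pd.DataFrame  # columns: patient_id, label, ga_weeks
    X: pd.DataFrame
    y: np.ndarray = field(repr=False)

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.y).sum())


# -- file I/O ---------------------------------------------------------------


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
    covariates_path=None,
) -> CohortTable:
    """Read a cohort table from delimited text.

    ``schema`` optionally maps file headers to the canonical names in
    :data:`METADATA_COLUMNS` (e.g. ``{"PatientID": "ID"}``).
    """
    df = pd.read_csv(path, sep=sep)
    if schema:
        df = df.rename(columns=dict(schema))
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file is missing required column {col!r}")
    df["GADiagnosis"] = pd.to_numeric(df["GADiagnosis"], errors="coerce")
    covariates = read_covariates(covariates_path, sep=sep) if covariates_path else None
    return CohortTable(df, covariates=covariates)


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    cohort.data.to_csv(path, sep=sep, index=False)


def read_covariates(path, sep: str = ",") -> pd.DataFrame:
    """Read the optional per-patient covariate table (BMI, smoking, age, parity)."""
    df = pd.read_csv(path, sep=sep)
    for col in COVARIATE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"covariate file is missing required column {col!r}")
    return df.set_index("ID")


# -- contrasts and interval views ------------------------------------------


def define_contrast(cohort: CohortTable, mode: str) -> CohortTable:
    """Label every patient case/control/excluded for the requested contrast.

    Modes: ``all_early_pe`` (early PE vs normal), ``mvm_only`` /
    ``severe_only`` (subgroup cases vs normal, other cases excluded), and
    ``early_vs_control_plus_late`` (early PE vs normal + late PE combined).
    """
    if mode not in CONTRAST_MODES:
        raise ConfigurationError(f"unknown contrast mode {mode!r}; choose from {CONTRAST_MODES}")
    pats = cohort.patients
    early = pats["EarlyPE"] == 1
    late = (
        pats[LATE_PE_COLUMN] == 1
        if LATE_PE_COLUMN in pats.columns
        else pd.Series(False, index=pats.index)
    )
    normal = ~early & ~late

    if mode == "all_early_pe":
        case = early
        control = normal
    elif mode == "mvm_only":
        case = pats["EarlyPE_MVM"] == 1
        control = normal
    elif mode == "severe_only":
        case = pats["EarlyPE_Severe"] == 1
        control = normal
    else:  # early_vs_control_plus_late
        if not late.any():
            raise ConfigurationError(
                "contrast 'early_vs_control_plus_late' requires late-PE records "
                f"(column {LATE_PE_COLUMN!r} with at least one flagged patient)"
            )
        case = early
        control = normal | late

    labels = pd.Series("excluded", index=pats.index, name="label")
    labels[control] = "control"
    labels[case] = "case"
    if int(case.sum()) == 0:
        warnings.warn(f"contrast {mode!r} retained zero cases", UserWarning, stacklevel=2)
    return cohort.with_labels(labels, mode)


def select_interval_view(
    cohort: CohortTable,
    interval: str,
    scheme: GAIntervalScheme = DEFAULT_SCHEME,
) -> IntervalView:
    """Pick one pre-diagnosis sample per patient inside a GA interval.

    Samples at or after a patient's diagnosis GA are removed first.  Among a
    patient's remaining in-interval samples the one closest to the interval
    midpoint is chosen, ties resolved to the earlier sample.  Patients with
    no eligible sample are absent from the view.
    """
    if cohort.labels is None or cohort.contrast is None:
        raise ConfigurationError("cohort must be labeled by define_contrast first")
    lo, hi = scheme.bounds(interval)  # raises KeyError on unknown label
    mid = scheme.midpoint(interval)

    df = cohort.data
    labels = cohort.labels
    keep = df["ID"].map(labels).isin(["case", "control"])
    # strict censoring: samples taken at the diagnosis visit are excluded
    keep &= df["GADiagnosis"].isna() | (df["GA"] < df["GADiagnosis"])
    in_interval = df["GA"].apply(lambda g: scheme.assign(g) == interval)
    eligible = df.loc[keep & in_interval].copy()

    eligible["__dist"] = (eligible["GA"] - mid).abs()
    eligible = eligible.sort_values(["ID", "__dist", "GA"], kind="mergesort")
    chosen = eligible.drop_duplicates("ID", keep="first").drop(columns="__dist")
    chosen = chosen.sort_values("ID", kind="mergesort").reset_index(drop=True)

    pat = pd.DataFrame(
        {
            "patient_id": chosen["ID"].to_numpy(),
            "label": chosen["ID"].map(labels).to_numpy(),
            "ga_weeks": chosen["GA"].to_numpy(float),
        }
    )
    X = chosen[cohort.proteins].astype(float).reset_index(drop=True)
    y = (pat["label"] == "case").to_numpy(int)
    return IntervalView(interval=interval, contrast=cohort.contrast, patients=pat, X=X, y=y)


def interval_occupancy(
    cohort: CohortTable, scheme: GAIntervalScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Patients contributing a pre-diagnosis sample to each interval, by group."""
    if cohort.labels is None:
        cohort = define_contrast(cohort, "all_early_pe")
    rows = []
    for label in scheme.labels:
        view = select_interval_view(cohort, label, scheme)
        rows.append({"interval": label, "cases": view.n_cases, "controls": view.n_controls})
    return pd.DataFrame(rows)
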