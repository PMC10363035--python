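"""Trial data containers, CSV I/O, and the evaluability filter.

Canonical long-format schema (all files comma-separated, UTF-8, header row):

* ``tumor.csv``     — subject_id, arm, time_weeks, sld_mm
* ``covariates.csv``— subject_id, albumin, ecog, race, n_met_sites, nlr,
  liver_met, baseline_sld, line_of_therapy, sex
* ``os.csv``        — subject_id, os_days, event (1 = death, 0 = censored)

Tumor-size times are stored in weeks relative to treatment start (negative
times are screening scans); survival times in days.  The single conversion
constant between the two unit systems is :data:`DAYS_PER_WEEK`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Fixed conversion between the tumor-model time unit (weeks) and the
#: survival time unit (days).
DAYS_PER_WEEK = 7.0

ARMS = ("treatment", "control")
RACE_LEVELS = ("Asian", "non-Asian")
LIVER_LEVELS = ("yes", "no")
LINE_LEVELS = ("1", "2+")
SEX_LEVELS = ("female", "male")

TUMOR_COLUMNS = ["subject_id", "arm", "time_weeks", "sld_mm"]
COVARIATE_COLUMNS = [
    "subject_id",
    "albumin",
    "ecog",
    "race",
    "n_met_sites",
    "nlr",
    "liver_met",
    "baseline_sld",
    "line_of_therapy",
    "sex",
]
OS_COLUMNS = ["subject_id", "os_days", "event"]

#: Number of metastatic sites is capped at this value when entering the
#: survival model (sites beyond the cap carry no additional prognostic
#: weight in the model).
MET_SITES_CAP = 5


class SchemaError(ValueError):
    """A mandatory column is missing or a file cannot be parsed."""


class ValidationError(ValueError):
    """Values violate the documented schema (unknown level, bad range)."""


@dataclass(frozen=True)
class CSVDialect:
    """Column-name and categorical-level mapping for non-canonical CSVs.

    ``column_map`` maps file column names to canonical names; ``arm_map``,
    ``race_map`` etc. map file-level category labels onto the canonical
    levels.  An empty dialect reads the canonical schema as-is.
    """

    column_map: Mapping[str, str] = field(default_factory=dict)
    arm_map: Mapping[str, str] = field(default_factory=dict)
    race_map: Mapping[str, str] = field(default_factory=dict)
    liver_map: Mapping[str, str] = field(default_factory=dict)
    line_map: Mapping[str, str] = field(default_factory=dict)
    sex_map: Mapping[str, str] = field(default_factory=dict)


@dataclass
class TrialDataset:
    """In-memory trial: tumor-size records, baseline covariates, OS outcomes.

    ``tumor`` holds one row per (subject, visit); ``covariates`` and ``os``
    one row per subject.  Subjects in ``covariates``/``os`` must appear in
    ``tumor``.
    """

    tumor: pd.DataFrame
    covariates: pd.DataFrame
    os: pd.DataFrame

    def __post_init__(self) -> None:
        self.tumor = self.tumor.reset_index(drop=True)
        self.covariates = self.covariates.reset_index(drop=True)
        self.os = self.os.reset_index(drop=True)
        _validate_tumor(self.tumor)
        _validate_covariates(self.covariates)
        _validate_os(self.os)
        tumor_ids = set(self.tumor["subject_id"])
        for name, df in (("covariates", self.covariates), ("os", self.os)):
            extra = set(df["subject_id"]) - tumor_ids
            if extra:
                raise ValidationError(
                    f"{name} contains subjects absent from tumor records: "
                    f"{sorted(map(str, extra))[:10]}"
                )

    @property
    def subject_ids(self) -> list:
        return list(pd.unique(self.tumor["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.tumor["subject_id"].nunique()

    def subset(self, subject_ids) -> "TrialDataset":
        keep = set(subject_ids)
        return TrialDataset(
            tumor=self.tumor[self.tumor["subject_id"].isin(keep)],
            covariates=self.covariates[self.covariates["subject_id"].isin(keep)],
            os=self.os[self.os["subject_id"].isin(keep)],
        )

    def arm_of(self) -> pd.Series:
        """Series mapping subject_id -> arm."""
        return self.tumor.drop_duplicates("subject_id").set_index("subject_id")["arm"]


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s) {missing}")


def _check_levels(series: pd.Series, levels: tuple, what: str) -> None:
    bad = series[~series.isin(levels)]
    if len(bad):
        offenders = [
            f"row {i}: {v!r}" for i, v in bad.head(10).items()
        ]
        raise ValidationError(
            f"{what}: unknown level(s), expected one of {levels}: {offenders}"
        )


def _validate_tumor(df: pd.DataFrame) -> None:
    _require_columns(df, TUMOR_COLUMNS, "tumor records")
    _check_levels(df["arm"], ARMS, "tumor records: arm")
    if (df["sld_mm"] < 0).any():
        rows = df.index[df["sld_mm"] < 0].tolist()[:10]
        raise ValidationError(f"tumor records: negative sld_mm at rows {rows}")
    dup = df.duplicated(subset=["subject_id", "time_weeks"])
    if dup.any():
        rows = df.index[dup].tolist()[:10]
        raise ValidationError(
            f"tumor records: duplicate (subject_id, time_weeks) at rows {rows}"
        )
    n_arms = df.groupby("subject_id")["arm"].nunique()
    multi = n_arms[n_arms > 1]
    if len(multi):
        raise ValidationError(
            f"tumor records: subjects with multiple arms: {list(multi.index)[:10]}"
        )


def _validate_covariates(df: pd.DataFrame) -> None:
    _require_columns(df, COVARIATE_COLUMNS, "covariates")
    if df["subject_id"].duplicated().any():
        raise ValidationError("covariates: duplicate subject_id rows")
    _check_levels(df["race"], RACE_LEVELS, "covariates: race")
    _check_levels(df["liver_met"], LIVER_LEVELS, "covariates: liver_met")
    _check_levels(df["line_of_therapy"], LINE_LEVELS, "covariates: line_of_therapy")
    _check_levels(df["sex"], SEX_LEVELS, "covariates: sex")
    if not df["ecog"].isin([0, 1]).all():
        raise ValidationError("covariates: ecog must be 0 or 1 (1 meaning ECOG >= 1)")
    if (df["n_met_sites"] < 1).any():
        raise ValidationError("covariates: n_met_sites must be >= 1")
    for col in ("albumin", "nlr", "baseline_sld"):
        if (df[col] <= 0).any():
            raise ValidationError(f"covariates: {col} must be > 0")


def _validate_os(df: pd.DataFrame) -> None:
    _require_columns(df, OS_COLUMNS, "os outcomes")
    if df["subject_id"].duplicated().any():
        raise ValidationError("os outcomes: duplicate subject_id rows")
    if (df["os_days"] <= 0).any():
        raise ValidationError("os outcomes: os_days must be > 0")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("os outcomes: event must be 0 (censored) or 1 (death)")


def _apply_dialect(df: pd.DataFrame, dialect: CSVDialect) -> pd.DataFrame:
    if dialect.column_map:
        df = df.rename(columns=dict(dialect.column_map))
    for col, mapping in (
        ("arm", dialect.arm_map),
        ("race", dialect.race_map),
        ("liver_met", dialect.liver_map),
        ("line_of_therapy", dialect.line_map),
        ("sex", dialect.sex_map),
    ):
        if mapping and col in df.columns:
            df[col] = df[col].map(lambda v: dict(mapping).get(v, v))
    return df


def read_trial(
    path: str | Path,
    dialect: CSVDialect | None = None,
    tumor_file: str = "tumor.csv",
    covariates_file: str = "covariates.csv",
    os_file: str = "os.csv",
) -> TrialDataset:
    """Read a trial from a directory of canonical CSV files.

    Parameters
    ----------
    path
        Directory containing the three CSV files.
    dialect
        Optional column/level remapping applied before validation.

    Raises
    ------
    SchemaError
        If a file or mandatory column is missing.
    ValidationError
        If values violate the schema (offending rows are listed).
    """
    dialect = dialect or CSVDialect()
    path = Path(path)
    frames = {}
    for key, fname in (
        ("tumor", tumor_file),
        ("covariates", covariates_file),
        ("os", os_file),
    ):
        fpath = path / fname
        if not fpath.exists():
            raise SchemaError(f"missing input file: {fpath}")
        frames[key] = _apply_dialect(pd.read_csv(fpath), dialect)
    for col in ("time_weeks", "sld_mm"):
        if col in frames["tumor"].columns:
            frames["tumor"][col] = frames["tumor"][col].astype(float)
    cov = frames["covariates"]
    if "line_of_therapy" in cov.columns:
        # "1" must stay a categorical label, not become the integer 1
        cov["line_of_therapy"] = cov["line_of_therapy"].astype(str)
    return TrialDataset(**frames)


def write_trial(ds: TrialDataset, path: str | Path) -> dict[str, Path]:
    """Write a trial to the canonical three-file CSV layout; returns paths."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out = {
        "tumor": path / "tumor.csv",
        "covariates": path / "covariates.csv",
        "os": path / "os.csv",
    }
    ds.tumor[TUMOR_COLUMNS].to_csv(out["tumor"], index=False)
    ds.covariates[COVARIATE_COLUMNS].to_csv(out["covariates"], index=False)
    ds.os[OS_COLUMNS].to_csv(out["os"], index=False)
    return out


@dataclass
class EvaluabilityReport:
    """Outcome of the evaluability filter."""

    n_input: int
    n_retained: int
    excluded: pd.DataFrame  # subject_id, reason

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def filter_evaluable(ds: TrialDataset) -> tuple[TrialDataset, EvaluabilityReport]:
    """Restrict to subjects evaluable for tumor-dynamics modeling.

    A subject is evaluable when they have at least one baseline tumor-size
    record (time <= 0) and at least one post-baseline record (time > 0).
    Subjects with only baseline assessments are excluded.  The report lists
    every excluded subject with the reason.
    """
    grouped = ds.tumor.groupby("subject_id")["time_weeks"]
    has_baseline = grouped.min() <= 0
    has_post = grouped.max() > 0
    evaluable = has_baseline & has_post
    reasons = []
    for sid in evaluable.index[~evaluable]:
        if not has_baseline.loc[sid]:
            reasons.append((sid, "no baseline record (time <= 0)"))
        else:
            reasons.append((sid, "baseline-only (no post-baseline record)"))
    report = EvaluabilityReport(
        n_input=len(evaluable),
        n_retained=int(evaluable.sum()),
        excluded=pd.DataFrame(reasons, columns=["subject_id", "reason"]),
    )
    return ds.subset(evaluable.index[evaluable]), report


def baseline_sld(ds: TrialDataset) -> pd.Series:
    """Observed baseline SLD per subject: the record at time <= 0 closest to 0."""
    base = ds.tumor[ds.tumor["time_weeks"] <= 0]
    idx = base.groupby("subject_id")["time_weeks"].idxmax()
    return base.loc[idx].set_index("subject_id")["sld_mm"]


def cap_met_sites(n) -> int | np.ndarray:
    """Cap the number of metastatic sites at :data:`MET_SITES_CAP` (5).

    Accepts a scalar or an array; raises for values below 1.
    """
    arr = np.asarray(n)
    if (arr < 1).any():
        raise ValueError("number of metastatic sites must be >= 1")
    capped = np.minimum(arr, MET_SITES_CAP)
    if np.isscalar(n) or arr.ndim == 0:
        return int(capped)
    return capped


def missing_os_covariates(ds: TrialDataset) -> pd.DataFrame:
    """Subjects lacking covariates or OS outcomes, hence excluded from OS fitting."""
    ids = set(ds.subject_ids)
    cov_ids = set(ds.covariates["subject_id"])
    os_ids = set(ds.os["subject_id"])
    rows = []
    for sid in sorted(ids - cov_ids, key=str):
        rows.append((sid, "missing covariates"))
    for sid in sorted(ids - os_ids, key=str):
        rows.append((sid, "missing OS outcome"))
    return pd.DataFrame(rows, columns=["subject_id", "reason"])
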