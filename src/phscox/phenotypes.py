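"""Time-to-event progression phenotypes from EHR-style event tables.

A progression phenotype is the time from the first diagnosis of a
baseline condition (3-character ICD-10 code set) to the first subsequent
comorbidity diagnosis or surgical procedure (ICD-10 / OPCS-4 code set),
right-censored at death or at an administrative censoring date. Dates of
birth are reconstructed from month/year of birth as the first day of the
birth month, and a handful of registry sentinel dates receive fixed
corrections before any age is computed:

========== =====================================
1902-02-02 replaced by the date of birth
1903-03-03 replaced by date of birth + 6 months
2037-07-07 removed (date in the future)
1900-01-01 removed (unknown date)
========== =====================================

Events dated within a month before birth are moved to the date of
birth, and an age of exactly zero (event on the date of birth) is
recorded as one month, since the survival model requires strictly
positive times.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_SOURCES",
    "ProgressionDefinition",
    "ProgressionDataset",
    "CleaningReport",
    "DerivationReport",
    "compute_dob",
    "clean_event_dates",
    "age_at_event",
    "derive_progression",
    "check_case_thresholds",
]

EVENT_SOURCES = ("primary_care", "inpatient", "death", "self_report", "procedure")

DAYS_PER_YEAR = 365.25
MIN_AGE_YEARS = 1.0 / 12.0  # zero ages are recorded as one month

SENTINEL_TO_DOB = pd.Timestamp("1902-02-02")
SENTINEL_TO_DOB_PLUS_6M = pd.Timestamp("1903-03-03")
SENTINEL_FUTURE = pd.Timestamp("2037-07-07")
SENTINEL_UNKNOWN = pd.Timestamp("1900-01-01")


@dataclass
class ProgressionDefinition:
    """One baseline -> outcome phenotype pair with its censoring date.

    Diagnosis code sets are matched on the 3-character ICD-10 prefix;
    procedure (OPCS-4) codes are matched as exact strings. The case
    thresholds mirror common-disease progression screening: baselines
    need more than ``min_baseline_cases`` diagnosed individuals and
    outcomes more than ``min_outcome_cases`` events to be analysed.
    """

    baseline_codes: frozenset
    outcome_codes: frozenset
    censor_date: pd.Timestamp
    min_baseline_cases: int = 15_000
    min_outcome_cases: int = 400
    name: str = "progression"

    def __post_init__(self):
        self.baseline_codes = frozenset(self.baseline_codes)
        self.outcome_codes = frozenset(self.outcome_codes)
        if not self.baseline_codes or not self.outcome_codes:
            raise ValueError("baseline and outcome code sets must be non-empty")
        if self.baseline_codes & self.outcome_codes:
            raise ValueError("baseline and outcome code sets must be disjoint")
        self.censor_date = pd.Timestamp(self.censor_date)


def _matches(codes: pd.Series, codeset: frozenset) -> np.ndarray:
    """Exact match, or 3-character-prefix match for diagnosis-style sets."""
    exact = codes.isin(codeset)
    prefix = codes.str[:3].isin({c for c in codeset if len(c) == 3})
    return (exact | prefix).to_numpy()


@dataclass
class ProgressionDataset:
    """Per-person observation unit of the Cox model for one phenotype pair.

    ``y`` is years from baseline diagnosis to the outcome event or to
    censoring (strictly positive); ``status`` is 1 for an observed
    outcome and 0 for right censoring (administrative cutoff or death).
    ``covariates`` carries the adjustment variables (age at baseline
    diagnosis, sex, genotyping array, genetic PCs) row-aligned with
    ``person_ids``.
    """

    person_ids: np.ndarray
    y: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame
    name: str = "progression"

    def __post_init__(self):
        self.person_ids = np.asarray(self.person_ids)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.status = np.asarray(self.status, dtype=np.int64)
        n = len(self.person_ids)
        if not (len(self.y) == len(self.status) == len(self.covariates) == n):
            raise ValueError("misaligned progression dataset fields")
        if len(np.unique(self.person_ids)) != n:
            raise ValueError("duplicate person ids")
        if np.any(self.y <= 0):
            raise ValueError("all y must be > 0")
        if not np.all(np.isin(self.status, [0, 1])):
            raise ValueError("status must be 0/1")
        self.covariates = self.covariates.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.person_ids)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def age_at_baseline(self) -> np.ndarray:
        return self.covariates["age_at_baseline"].to_numpy()

    def covariate_matrix(self) -> np.ndarray:
        return self.covariates.to_numpy(dtype=np.float64)

    def to_tsv(self, path) -> None:
        out = pd.DataFrame({"person_id": self.person_ids, "y": self.y, "status": self.status})
        out = pd.concat([out, self.covariates.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str = "progression") -> "ProgressionDataset":
        df = pd.read_csv(path, sep="\t")
        cov = df.drop(columns=["person_id", "y", "status"])
        return cls(
            person_ids=df["person_id"].to_numpy(),
            y=df["y"].to_numpy(),
            status=df["status"].to_numpy(),
            covariates=cov,
            name=name,
        )


# ----------------------------------------------------------------------
# dates and ages
# ----------------------------------------------------------------------
def compute_dob(birth_month: int, birth_year: int) -> pd.Timestamp:
    """Date of birth as the first day of the birth month."""
    birth_month, birth_year = int(birth_month), int(birth_year)
    if not 1 <= birth_month <= 12:
        raise ValueError(f"birth month {birth_month} outside 1-12")
    return pd.Timestamp(year=birth_year, month=birth_month, day=1)


@dataclass
class CleaningReport:
    """Counts of each sentinel-date action taken by :func:`clean_event_dates`."""

    to_dob_1902: int = 0
    to_dob_plus_6m_1903: int = 0
    removed_2037: int = 0
    removed_1900: int = 0
    month_before_birth_to_dob: int = 0
    removed_pre_birth: int = 0
    unchanged: int = 0

    def total_actions(self) -> int:
        return (
            self.to_dob_1902
            + self.to_dob_plus_6m_1903
            + self.removed_2037
            + self.removed_1900
            + self.month_before_birth_to_dob
            + self.removed_pre_birth
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"action": list(self.__dict__), "count": list(self.__dict__.values())}
        ).to_csv(path, sep="\t", index=False)


def clean_event_dates(
    records: pd.DataFrame, dob: pd.Series
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the sentinel-date rules to an event table.

    ``records`` needs columns person_id, code, date, source; ``dob`` maps
    person_id -> date of birth. Sentinel replacements are applied first,
    future/unknown sentinel records are removed, and any remaining record
    dated within [DOB - 31 days, DOB) is moved to the DOB. Records dated
    more than 31 days before birth are removed (and counted) — they
    cannot yield a valid age. Cleaning is idempotent on its own output
    for cohorts born after the sentinel era.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    missing = ~rec["person_id"].isin(dob.index)
    if missing.any():
        raise KeyError(
            f"no date of birth for person(s) {sorted(set(rec.loc[missing, 'person_id']))[:5]}"
        )
    person_dob = pd.to_datetime(rec["person_id"].map(dob)).to_numpy()
    date = rec["date"].to_numpy()
    report = CleaningReport()

    m_1902 = date == np.datetime64(SENTINEL_TO_DOB)
    m_1903 = date == np.datetime64(SENTINEL_TO_DOB_PLUS_6M)
    m_2037 = date == np.datetime64(SENTINEL_FUTURE)
    m_1900 = date == np.datetime64(SENTINEL_UNKNOWN)
    report.to_dob_1902 = int(m_1902.sum())
    report.to_dob_plus_6m_1903 = int(m_1903.sum())
    report.removed_2037 = int(m_2037.sum())
    report.removed_1900 = int(m_1900.sum())

    date = np.where(m_1902, person_dob, date)
    plus6 = (pd.DatetimeIndex(person_dob) + pd.DateOffset(months=6)).to_numpy()
    date = np.where(m_1903, plus6, date)

    keep = ~(m_2037 | m_1900)
    handled = m_1902 | m_1903
    delta_days = (date - person_dob) / np.timedelta64(1, "D")
    m_month_before = keep & ~handled & (delta_days < 0) & (delta_days >= -31)
    m_pre_birth = keep & ~handled & (delta_days < -31)
    report.month_before_birth_to_dob = int(m_month_before.sum())
    report.removed_pre_birth = int(m_pre_birth.sum())
    date = np.where(m_month_before, person_dob, date)
    keep &= ~m_pre_birth
    report.unchanged = int((keep & ~handled & ~m_month_before).sum())

    rec["date"] = date
    rec = rec.loc[keep].reset_index(drop=True)
    return rec, report


def age_at_event(dob, event_date) -> float:
    """Age in years (days / 365.25); an age of exactly 0 becomes 1 month."""
    dob = pd.Timestamp(dob)
    event_date = pd.Timestamp(event_date)
    days = (event_date - dob).days
    if days < 0:
        raise ValueError(f"event date {event_date.date()} precedes DOB {dob.date()}")
    age = days / DAYS_PER_YEAR
    return MIN_AGE_YEARS if age == 0.0 else age


def _ages_vector(dates: np.ndarray, dobs: np.ndarray) -> np.ndarray:
    days = (dates - dobs) / np.timedelta64(1, "D")
    if np.any(days < 0):
        raise ValueError("event before DOB after cleaning")
    age = days / DAYS_PER_YEAR
    return np.where(age == 0.0, MIN_AGE_YEARS, age)


# ----------------------------------------------------------------------
# derivation
# ----------------------------------------------------------------------
@dataclass
class DerivationReport:
    """Exhaustive, disjoint partition of the cohort during derivation."""

    included: int = 0
    excluded_by_ordering: int = 0  # earliest outcome not after baseline
    no_baseline: int = 0

    @property
    def total(self) -> int:
        return self.included + self.excluded_by_ordering + self.no_baseline


def derive_progression(
    records: pd.DataFrame,
    definition: ProgressionDefinition,
    deaths: pd.Series,
    dob: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[ProgressionDataset, DerivationReport]:
    """Build (y, status) for one baseline -> outcome phenotype pair.

    For every person with at least one baseline-code event, t0 is the age
    at the earliest baseline event; the outcome age t1 is the age at the
    earliest outcome event on or before the censoring date, else the age
    at death or at the censoring date, whichever is earlier. status is 1
    only when an outcome event exists strictly after t0 — death counts
    as censoring. Persons whose earliest outcome age is at or before t0
    are excluded ("prior to" is read strictly), so every y is positive.

    ``covariates`` (indexed by person_id) supplies sex/array/PC columns;
    age at baseline diagnosis is always added as the first covariate.
    """
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    dob = pd.to_datetime(pd.Series(dob))
    deaths = pd.to_datetime(pd.Series(deaths)) if len(deaths) else pd.Series(dtype="datetime64[ns]")

    in_window = rec["date"] <= definition.censor_date
    base = rec.loc[in_window & _matches(rec["code"], definition.baseline_codes)]
    outc = rec.loc[in_window & _matches(rec["code"], definition.outcome_codes)]

    first_base = base.groupby("person_id")["date"].min()
    first_outc = outc.groupby("person_id")["date"].min()

    report = DerivationReport()
    all_persons = pd.Index(dob.index)
    report.no_baseline = int((~all_persons.isin(first_base.index)).sum())

    persons = first_base.index.to_numpy()
    dobs = dob.loc[persons].to_numpy()
    t0 = _ages_vector(first_base.to_numpy(), dobs)

    outc_dates = first_outc.reindex(persons).to_numpy()
    has_outcome = ~pd.isna(outc_dates)
    t1 = np.full(persons.shape, np.nan)
    if has_outcome.any():
        t1[has_outcome] = _ages_vector(outc_dates[has_outcome], dobs[has_outcome])

    death_dates = deaths.reindex(persons).to_numpy()
    cens_date = np.where(
        pd.isna(death_dates) | (death_dates > np.datetime64(definition.censor_date)),
        np.datetime64(definition.censor_date),
        death_dates,
    )
    t_cens = _ages_vector(cens_date, dobs)

    status = np.where(has_outcome & (t1 > t0), 1, 0)
    time_end = np.where(status == 1, t1, t_cens)
    excluded = (has_outcome & (t1 <= t0)) | ((status == 0) & (time_end <= t0))
    report.excluded_by_ordering = int(excluded.sum())

    keep = ~excluded
    report.included = int(keep.sum())
    if report.included == 0:
        raise ValueError(f"{definition.name}: derivation produced an empty dataset")

    persons_k = persons[keep]
    cov = pd.DataFrame({"age_at_baseline": t0[keep]})
    if covariates is not None:
        extra = covariates.reindex(persons_k).reset_index(drop=True)
        cov = pd.concat([cov, extra], axis=1)
    return (
        ProgressionDataset(
            person_ids=persons_k,
            y=time_end[keep] - t0[keep],
            status=status[keep],
            covariates=cov,
            name=definition.name,
        ),
        report,
    )


@dataclass
class ThresholdCheck:
    passed: bool
    n_baseline: int
    n_cases: int


def check_case_thresholds(
    dataset: ProgressionDataset, definition: ProgressionDefinition
) -> ThresholdCheck:
    """Strictly-more-than case-count screen for a derived phenotype."""
    n_baseline = len(dataset)
    n_cases = dataset.n_cases
    passed = (
        n_baseline > definition.min_baseline_cases
        and n_cases > definition.min_outcome_cases
    )
    return ThresholdCheck(passed=passed, n_baseline=n_baseline, n_cases=n_cases)
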