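"""Long-format longitudinal growth tables: reading, validation, inclusion rules.

One row is one measurement: subject id, sex (F/M), decimal age in years,
stature in centimetres.  A :class:`Cohort` is the validated, subject-indexed
container every downstream stage consumes.  Validation is strict: a row with
an out-of-range or unparseable value aborts the read rather than being
dropped, because growth modelling is sensitive to silent data loss.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DuplicateAgeError,
    FormatError,
    ParseError,
    RecordValidationError,
)

__all__ = [
    "Cohort",
    "InclusionCriteria",
    "read_long_csv",
    "write_long_csv",
    "apply_inclusion_filter",
    "measurement_count_table",
]

log = logging.getLogger(__name__)

COLUMNS = ("id", "sex", "age_years", "stature_cm")

AGE_BOUNDS = (0.0, 30.0)
STATURE_BOUNDS = (50.0, 230.0)

_SEX_CODES = {
    "f": "F", "female": "F", "0": "F",
    "m": "M", "male": "M", "1": "M",
}


def _normalize_sex(value) -> str:
    code = _SEX_CODES.get(str(value).strip().lower())
    if code is None:
        raise RecordValidationError(f"unrecognised sex code {value!r}")
    return code


@dataclass(frozen=True)
class Cohort:
    """Validated long-format growth table, sorted by subject then age."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table is missing columns {missing}")
        df = df.loc[:, list(COLUMNS)].copy()
        df["id"] = df["id"].astype(str)
        df["sex"] = df["sex"].map(_normalize_sex)
        for col, (lo, hi) in (("age_years", AGE_BOUNDS), ("stature_cm", STATURE_BOUNDS)):
            vals = np.asarray(df[col], dtype=float)
            if not np.all(np.isfinite(vals)):
                bad = df.index[~np.isfinite(vals)][0]
                raise RecordValidationError(f"non-finite {col} at row {bad}")
            out = (vals <= lo) | (vals >= hi)
            if out.any():
                bad = df.index[out][0]
                raise RecordValidationError(
                    f"{col}={vals[out][0]} outside ({lo}, {hi}) at row {bad}"
                )
            df[col] = vals
        df = df.sort_values(["id", "age_years"], kind="mergesort").reset_index(drop=True)
        dup = df.duplicated(subset=["id", "age_years"])
        if dup.any():
            row = df.loc[dup].iloc[0]
            raise DuplicateAgeError(
                f"subject {row['id']!r} has two measurements at age {row['age_years']}"
            )
        n_sex = df.groupby("id")["sex"].nunique()
        if (n_sex > 1).any():
            sid = n_sex.index[n_sex > 1][0]
            raise RecordValidationError(f"subject {sid!r} has more than one sex code")
        object.__setattr__(self, "data", df)

    # -- accessors --------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["id"]))

    @property
    def n_subjects(self) -> int:
        return self.data["id"].nunique()

    def records_for(self, subject_id: str) -> pd.DataFrame:
        return self.data[self.data["id"] == subject_id]

    def sex_of(self, subject_id: str) -> str:
        return self.records_for(subject_id)["sex"].iloc[0]

    def for_sex(self, sex: str) -> "Cohort":
        sex = _normalize_sex(sex)
        return Cohort(self.data[self.data["sex"] == sex])

    def counts_per_subject(self) -> pd.Series:
        return self.data.groupby("id", sort=False).size()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort inclusion rules for adequate pubertal coverage.

    Rule (a): at least ``min_measurements`` records with age inside the
    sex-specific ``pubertal_window`` (closed interval).
    Rule (b): first record age inside the sex-specific ``entry_window``.
    Rule (c): last record age >= sex-specific ``min_followup_age``.
    """

    min_measurements: int = 4
    pubertal_window: dict = field(
        default_factory=lambda: {"F": (9.9, 14.0), "M": (10.9, 15.0)}
    )
    entry_window: dict = field(default_factory=lambda: {"F": (6.0, 9.9), "M": (6.0, 10.9)})
    min_followup_age: dict = field(default_factory=lambda: {"F": 14.0, "M": 15.0})

    def __post_init__(self) -> None:
        if self.min_measurements < 1:
            raise ConfigurationError("min_measurements must be >= 1")
        for window in (self.pubertal_window, self.entry_window):
            for sex, (lo, hi) in window.items():
                if not lo < hi:
                    raise ConfigurationError(f"window for {sex} must have lower < upper")


def read_long_csv(path, column_map: dict | None = None) -> Cohort:
    """Read a long-format growth CSV into a validated :class:`Cohort`.

    ``column_map`` maps the file's column names onto the canonical
    ``id, sex, age_years, stature_cm``, e.g. ``{"child": "id"}``.
    """
    raw = pd.read_csv(path, dtype=str)
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in ("age_years", "stature_cm"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            row = int(raw.index[bad][0]) + 2
            raise ParseError(f"{path}: non-numeric {col} value {raw[col][bad].iloc[0]!r} at line {row}")
        if converted.isna().any():
            row = int(raw.index[converted.isna()][0]) + 2
            raise ParseError(f"{path}: missing {col} value at line {row}")
        raw[col] = converted
    cohort = Cohort(raw)
    log.info("read %d records / %d subjects from %s", cohort.n_records, cohort.n_subjects, path)
    return cohort


def write_long_csv(cohort: Cohort, path) -> None:
    """Write a cohort back to the canonical CSV dialect (full precision)."""
    cohort.data.to_csv(path, index=False, float_format="%.12g")


def apply_inclusion_filter(
    cohort: Cohort, criteria: InclusionCriteria | None = None
) -> tuple[Cohort, pd.DataFrame]:
    """Keep subjects satisfying all three inclusion rules.

    Returns the filtered cohort (row selection only, records untouched) and
    an exclusion report with one row per *excluded* subject and boolean
    columns ``rule_a, rule_b, rule_c`` (True = rule satisfied).
    """
    criteria = criteria or InclusionCriteria()
    keep: list[str] = []
    report_rows = []
    for sid, grp in cohort.data.groupby("id", sort=False):
        sex = grp["sex"].iloc[0]
        ages = grp["age_years"].to_numpy()
        lo, hi = criteria.pubertal_window[sex]
        rule_a = int(((ages >= lo) & (ages <= hi)).sum()) >= criteria.min_measurements
        e_lo, e_hi = criteria.entry_window[sex]
        rule_b = e_lo <= ages[0] <= e_hi
        rule_c = ages[-1] >= criteria.min_followup_age[sex]
        if rule_a and rule_b and rule_c:
            keep.append(sid)
        else:
            report_rows.append({"id": sid, "rule_a": rule_a, "rule_b": rule_b, "rule_c": rule_c})
    report = pd.DataFrame(report_rows, columns=["id", "rule_a", "rule_b", "rule_c"])
    filtered = Cohort(cohort.data[cohort.data["id"].isin(keep)])
    if filtered.n_subjects == 0:
        warnings.warn("inclusion filter removed every subject", stacklevel=2)
    log.info(
        "inclusion filter kept %d/%d subjects", filtered.n_subjects, cohort.n_subjects
    )
    return filtered, report


def measurement_count_table(cohort: Cohort) -> pd.DataFrame:
    """Per-sex distribution of the number of measurements per subject.

    Rows are measurement counts; columns ``all``, ``F``, ``M`` give the
    number of subjects with that many records.  Column sums equal the
    subject counts (the table partitions the cohort).
    """
    per_subject = cohort.data.groupby("id", sort=False).agg(
        n=("age_years", "size"), sex=("sex", "first")
    )
    counts = sorted(per_subject["n"].unique())
    rows = []
    for c in counts:
        sub = per_subject[per_subject["n"] == c]
        rows.append(
            {
                "n_measurements": int(c),
                "all": len(sub),
                "F": int((sub["sex"] == "F").sum()),
                "M": int((sub["sex"] == "M").sum()),
            }
        )
    return pd.DataFrame(rows, columns=["n_measurements", "all", "F", "M"])
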