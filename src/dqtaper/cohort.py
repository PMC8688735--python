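"""Cohort container, table schemas, validation and delimited-text I/O.

A cohort is four tidy tables (comma-separated, UTF-8, header row):

``patients``
    patient_id, group {tapering, withdrawal}, diagnosis {AS, nr-axSpA},
    sex {male, female}, age (years, integer >= 16), duration (months),
    hla_b27 (0/1), smoking (0/1)
``visits``
    patient_id, month, asdas_crp, asdas_esr, basdai, basfi, crp, esr.
    ASDAS-CRP is mandatory at every canonical month (status
    classification consumes it); the other clinical fields are optional
    (blank cells).
``mri``
    patient_id, month, sparcc, fat, erosion, backfill, measured (0/1).
    Months 0, 12 and 24 must be present and measured; interior months
    may be absent (they are imputed downstream by linear interpolation).
``doses``
    patient_id, month, drug, actual_dose, actual_interval.  A dose of 0
    encodes withdrawal.

Booleans are serialized as 0/1 and missing optional values as empty
cells, so a round-trip through :func:`write_cohort` / :func:`read_cohort`
is lossless field for field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CANONICAL_MONTHS, MRI_SCORES, SCORE_BOUNDS
from .errors import ValidationError

__all__ = [
    "Cohort",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "baseline_table",
    "TABLE_FILES",
]

#: Table name -> file name used by read_cohort/write_cohort.
TABLE_FILES: dict[str, str] = {
    "patients": "patients.csv",
    "visits": "visits.csv",
    "mri": "mri.csv",
    "doses": "doses.csv",
}

PATIENT_COLUMNS = (
    "patient_id",
    "group",
    "diagnosis",
    "sex",
    "age",
    "duration",
    "hla_b27",
    "smoking",
)
VISIT_COLUMNS = (
    "patient_id",
    "month",
    "asdas_crp",
    "asdas_esr",
    "basdai",
    "basfi",
    "crp",
    "esr",
)
MRI_COLUMNS = ("patient_id", "month", *MRI_SCORES, "measured")
DOSE_COLUMNS = ("patient_id", "month", "drug", "actual_dose", "actual_interval")

_ENUMS = {
    "group": ("tapering", "withdrawal"),
    "diagnosis": ("AS", "nr-axSpA"),
    "sex": ("male", "female"),
}

#: Optional visit fields and their admissible ranges.
_VISIT_RANGES = {
    "asdas_crp": (0.0, np.inf),
    "asdas_esr": (0.0, np.inf),
    "basdai": (0.0, 10.0),
    "basfi": (0.0, 10.0),
    "crp": (0.0, np.inf),
    "esr": (0.0, np.inf),
}


@dataclass
class Cohort:
    """The four cohort tables plus the validation bounds in force."""

    patients: pd.DataFrame
    visits: pd.DataFrame
    mri: pd.DataFrame
    doses: pd.DataFrame
    score_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SCORE_BOUNDS)
    )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def equals(self, other: "Cohort") -> bool:
        """Field-for-field equality of the four tables (order-insensitive)."""

        def canon(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
            return df.sort_values(keys, kind="mergesort").reset_index(drop=True)

        return (
            canon(self.patients, ["patient_id"]).equals(
                canon(other.patients, ["patient_id"])
            )
            and canon(self.visits, ["patient_id", "month"]).equals(
                canon(other.visits, ["patient_id", "month"])
            )
            and canon(self.mri, ["patient_id", "month"]).equals(
                canon(other.mri, ["patient_id", "month"])
            )
            and canon(self.doses, ["patient_id", "month"]).equals(
                canon(other.doses, ["patient_id", "month"])
            )
        )


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"table {table!r}: missing columns {missing}")


def _check_months(df: pd.DataFrame, table: str) -> None:
    bad = df.loc[~df["month"].isin(CANONICAL_MONTHS)]
    if len(bad):
        row = bad.iloc[0]
        raise ValidationError(
            f"table {table!r}, patient {row['patient_id']!r}: month "
            f"{row['month']!r} is not on the canonical grid {CANONICAL_MONTHS}"
        )


def _check_unique(df: pd.DataFrame, keys: list[str], table: str) -> None:
    dup = df.loc[df.duplicated(keys)]
    if len(dup):
        row = dup.iloc[0]
        raise ValidationError(
            f"table {table!r}: duplicate key "
            f"{tuple(row[k] for k in keys)!r} on {keys}"
        )


def validate_cohort(cohort: Cohort) -> Cohort:
    """Check every typed invariant; raise ValidationError naming the record.

    Checks: column presence, enum membership, key uniqueness,
    referential integrity against the patients table, the canonical
    month grid, score bounds, mandatory ASDAS-CRP at every grid month,
    and measured MRI at months 0/12/24.
    """
    p, v, m, d = cohort.patients, cohort.visits, cohort.mri, cohort.doses
    _require_columns(p, PATIENT_COLUMNS, "patients")
    _require_columns(v, VISIT_COLUMNS, "visits")
    _require_columns(m, MRI_COLUMNS, "mri")
    _require_columns(d, DOSE_COLUMNS, "doses")

    _check_unique(p, ["patient_id"], "patients")
    for col, levels in _ENUMS.items():
        bad = p.loc[~p[col].isin(levels)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"table 'patients', patient {row['patient_id']!r}: "
                f"{col}={row[col]!r} not in {levels}"
            )
    if len(p):
        if (p["age"] < 16).any():
            pid = p.loc[p["age"] < 16, "patient_id"].iloc[0]
            raise ValidationError(f"patient {pid!r}: age < 16")
        if (p["duration"] < 0).any():
            pid = p.loc[p["duration"] < 0, "patient_id"].iloc[0]
            raise ValidationError(f"patient {pid!r}: negative duration")
        for col in ("hla_b27", "smoking"):
            if not p[col].isin([0, 1]).all():
                pid = p.loc[~p[col].isin([0, 1]), "patient_id"].iloc[0]
                raise ValidationError(
                    f"patient {pid!r}: {col} must be 0/1"
                )

    known = set(p["patient_id"])
    for table, df in (("visits", v), ("mri", m), ("doses", d)):
        unknown = df.loc[~df["patient_id"].isin(known)]
        if len(unknown):
            raise ValidationError(
                f"table {table!r}: patient_id "
                f"{unknown['patient_id'].iloc[0]!r} not in patients table"
            )
        _check_months(df, table)
        _check_unique(df, ["patient_id", "month"], table)

    # Visits: ranges, and mandatory ASDAS-CRP on the full grid.
    for col, (lo, hi) in _VISIT_RANGES.items():
        vals = v[col]
        bad = v.loc[vals.notna() & ((vals < lo) | (vals > hi))]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"table 'visits', patient {row['patient_id']!r} month "
                f"{row['month']}: {col}={row[col]!r} outside [{lo}, {hi}]"
            )
    have = v.loc[v["asdas_crp"].notna()]
    counts = have.groupby("patient_id")["month"].apply(set)
    for pid in sorted(known):
        got = counts.get(pid, set())
        missing = [mm for mm in CANONICAL_MONTHS if mm not in got]
        if missing:
            raise ValidationError(
                f"patient {pid!r}: ASDAS-CRP missing at months {missing} "
                "(mandatory at every canonical month)"
            )

    # MRI: score bounds and the measured-at-0/12/24 rule.
    for score in MRI_SCORES:
        lo, hi = cohort.score_bounds[score]
        vals = m[score]
        bad = m.loc[vals.notna() & ((vals < lo) | (vals > hi))]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"table 'mri', patient {row['patient_id']!r} month "
                f"{row['month']}: {score}={row[score]!r} outside [{lo}, {hi}]"
            )
    if len(m) and not m["measured"].isin([0, 1]).all():
        row = m.loc[~m["measured"].isin([0, 1])].iloc[0]
        raise ValidationError(
            f"table 'mri', patient {row['patient_id']!r} month "
            f"{row['month']}: measured must be 0/1"
        )
    anchor = m.loc[(m["measured"] == 1)]
    anchor_months = anchor.groupby("patient_id")["month"].apply(set)
    for pid in sorted(known):
        got = anchor_months.get(pid, set())
        missing = [mm for mm in (0, 12, 24) if mm not in got]
        if missing:
            raise ValidationError(
                f"patient {pid!r}: measured MRI required at months 0/12/24, "
                f"missing {missing}"
            )

    # Doses: non-negative dose, positive interval.
    if len(d):
        bad = d.loc[(d["actual_dose"] < 0) | (d["actual_interval"] <= 0)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"table 'doses', patient {row['patient_id']!r} month "
                f"{row['month']}: dose must be >= 0 and interval > 0"
            )
    return cohort


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"table {table!r}: file not found: {path}")
    df = pd.read_csv(path)
    if "patient_id" in df.columns:
        df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_cohort(
    directory: str | Path,
    score_bounds: dict[str, tuple[float, float]] | None = None,
) -> Cohort:
    """Read and validate the four cohort tables from ``directory``."""
    directory = Path(directory)
    frames = {}
    for table, fname in TABLE_FILES.items():
        frames[table] = _read_table(directory / fname, table)
    cohort = Cohort(
        patients=frames["patients"],
        visits=frames["visits"],
        mri=frames["mri"],
        doses=frames["doses"],
    )
    if score_bounds is not None:
        cohort = replace(cohort, score_bounds=dict(score_bounds))
    return validate_cohort(cohort)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV; returns the paths written."""
    validate_cohort(cohort)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for table, fname in TABLE_FILES.items():
        path = directory / fname
        getattr(cohort, table).to_csv(path, index=False)
        paths[table] = path
    return paths


def baseline_table(cohort: Cohort) -> pd.DataFrame:
    """One row per patient: baseline covariates + month-0 clinical/MRI scores.

    Adds the reference-coded indicator columns used by the treatment
    models: sex_male, diagnosis_as (reference levels female, nr-axSpA;
    hla_b27 and smoking are already 0/1 with negative/non-smoker as 0).
    """
    p = cohort.patients.copy()
    p["sex_male"] = (p["sex"] == "male").astype(int)
    p["diagnosis_as"] = (p["diagnosis"] == "AS").astype(int)
    v0 = cohort.visits.loc[cohort.visits["month"] == 0].drop(columns=["month"])
    m0 = cohort.mri.loc[cohort.mri["month"] == 0].drop(
        columns=["month", "measured"]
    )
    out = p.merge(v0, on="patient_id", how="left").merge(
        m0, on="patient_id", how="left"
    )
    return out
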