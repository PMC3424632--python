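"""Core data model and CSV I/O for reading-level and subject-level tables.

Two on-disk tables are used throughout:

* a *readings* table, one row per cuff inflation, with columns
  ``subject_id,time_min,sbp,dbp[,hr]``;
* a *subjects* table, one row per participant, with columns
  ``id,sex,age,bmi,cholesterol,outcome`` (``cholesterol`` may be blank).

Times are minutes since each subject's recording start.  Conversion from
wall-clock timestamps is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, ValidationError

#: Default maximum recording duration accepted, in minutes (26 h).
MAX_DURATION_MIN = 26 * 60.0

READINGS_COLUMNS = ("subject_id", "time_min", "sbp", "dbp")
SUBJECTS_COLUMNS = ("id", "sex", "age", "bmi", "cholesterol", "outcome")


@dataclass(frozen=True)
class BPReading:
    """A single timed blood-pressure measurement.

    Parameters
    ----------
    time_min
        Minutes since the start of the subject's recording (non-negative).
    systolic, diastolic
        Pressures in mmHg.  ``systolic`` must exceed ``diastolic``.
    heart_rate
        Beats per minute; optional.
    """

    time_min: float
    systolic: float
    diastolic: float
    heart_rate: float | None = None

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValidationError(f"time_min must be >= 0, got {self.time_min}")
        if self.systolic <= self.diastolic:
            raise ValidationError(
                f"systolic ({self.systolic}) must exceed diastolic ({self.diastolic})"
            )


@dataclass(frozen=True)
class ABPRecording:
    """An ordered 24-h ambulatory recording for one subject."""

    subject_id: str
    readings: tuple[BPReading, ...]
    max_duration_min: float = field(default=MAX_DURATION_MIN, compare=False)

    def __post_init__(self) -> None:
        times = [r.time_min for r in self.readings]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"subject {self.subject_id}: reading times must be strictly increasing"
            )
        if times and times[-1] - times[0] > self.max_duration_min:
            raise ValidationError(
                f"subject {self.subject_id}: duration "
                f"{times[-1] - times[0]:.1f} min exceeds {self.max_duration_min} min"
            )

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time_min for r in self.readings], dtype=float)

    @property
    def systolic(self) -> np.ndarray:
        return np.array([r.systolic for r in self.readings], dtype=float)

    @property
    def diastolic(self) -> np.ndarray:
        return np.array([r.diastolic for r in self.readings], dtype=float)

    @property
    def heart_rate(self) -> np.ndarray | None:
        hr = [r.heart_rate for r in self.readings]
        if any(h is None for h in hr):
            return None
        return np.array(hr, dtype=float)

    @classmethod
    def from_arrays(
        cls,
        subject_id: str,
        times: Sequence[float],
        systolic: Sequence[float],
        diastolic: Sequence[float],
        heart_rate: Sequence[float] | None = None,
        max_duration_min: float = MAX_DURATION_MIN,
    ) -> "ABPRecording":
        hr = heart_rate if heart_rate is not None else [None] * len(times)
        readings = tuple(
            BPReading(float(t), float(s), float(d), None if h is None else float(h))
            for t, s, d, h in zip(times, systolic, diastolic, hr)
        )
        return cls(subject_id, readings, max_duration_min)


@dataclass(frozen=True)
class SubjectRecord:
    """Subject-level covariates and the binary outcome (1 = cardiovascular death)."""

    subject_id: str
    sex: int
    age: float
    bmi: float
    cholesterol: float  # NaN when missing
    outcome: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValidationError(f"outcome must be 0 or 1, got {self.outcome!r}")
        if self.age <= 0:
            raise ValidationError(f"age must be > 0, got {self.age}")

    @property
    def cholesterol_missing(self) -> bool:
        return bool(np.isnan(self.cholesterol))


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _coerce_numeric(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError(
            f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
            f"{col!r} at line {row}",
            row=row,
        )
    return out


def read_readings(
    path,
    delimiter: str = ",",
    max_duration_min: float = MAX_DURATION_MIN,
) -> list[ABPRecording]:
    """Read a readings CSV into one :class:`ABPRecording` per subject.

    Rows may appear in any order; readings are sorted by time within each
    subject.  Two rows sharing a (subject, time) pair are rejected: monitors
    emit distinct timestamps, so a duplicate indicates a corrupt export.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype={"subject_id": str})
    _require_columns(df, READINGS_COLUMNS, str(path))
    for col in ("time_min", "sbp", "dbp"):
        df[col] = _coerce_numeric(df, col, str(path))
    has_hr = "hr" in df.columns
    if has_hr:
        df["hr"] = _coerce_numeric(df, "hr", str(path))

    dup = df.duplicated(subset=["subject_id", "time_min"], keep=False)
    if dup.any():
        sid = df.loc[dup, "subject_id"].iloc[0]
        t = df.loc[dup, "time_min"].iloc[0]
        raise ValidationError(
            f"duplicate reading for subject {sid!r} at time_min={t}"
        )

    recordings = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("time_min")
        hr = grp["hr"].to_numpy() if has_hr else None
        if hr is not None and np.isnan(hr).all():
            hr = None
        recordings.append(
            ABPRecording.from_arrays(
                str(sid),
                grp["time_min"].to_numpy(),
                grp["sbp"].to_numpy(),
                grp["dbp"].to_numpy(),
                hr,
                max_duration_min=max_duration_min,
            )
        )
    return recordings


def write_readings(recordings: Iterable[ABPRecording], path, delimiter: str = ",") -> None:
    """Write recordings back to the readings CSV dialect (inverse of read)."""
    rows = []
    for rec in recordings:
        for r in rec.readings:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "time_min": r.time_min,
                    "sbp": r.systolic,
                    "dbp": r.diastolic,
                    "hr": r.heart_rate,
                }
            )
    df = pd.DataFrame(rows, columns=["subject_id", "time_min", "sbp", "dbp", "hr"])
    if df["hr"].isna().all():
        df = df.drop(columns=["hr"])
    df.to_csv(path, sep=delimiter, index=False)


def read_subjects(path, delimiter: str = ",") -> pd.DataFrame:
    """Read the subject-level table.

    Blank cholesterol cells become NaN (explicit missing markers); the
    outcome column must be coded 0/1.
    """
    df = pd.read_csv(path, delimiter=delimiter, dtype={"id": str})
    _require_columns(df, SUBJECTS_COLUMNS, str(path))
    for col in ("sex", "age", "bmi", "cholesterol", "outcome"):
        df[col] = _coerce_numeric(df, col, str(path))
    bad = ~df["outcome"].isin([0, 1])
    if bad.any():
        raise ValidationError(
            f"{path}: outcome must be 0 or 1, got {df['outcome'][bad].iloc[0]!r}"
        )
    df["outcome"] = df["outcome"].astype(int)
    df["sex"] = df["sex"].astype(int)
    return df.reset_index(drop=True)


def write_subjects(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df.to_csv(path, sep=delimiter, index=False, columns=list(SUBJECTS_COLUMNS))


def subjects_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    """Convert a subjects table into validated :class:`SubjectRecord` objects."""
    return [
        SubjectRecord(
            subject_id=str(row.id),
            sex=int(row.sex),
            age=float(row.age),
            bmi=float(row.bmi),
            cholesterol=float(row.cholesterol) if pd.notna(row.cholesterol) else float("nan"),
            outcome=int(row.outcome),
        )
        for row in df.itertuples(index=False)
    ]
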