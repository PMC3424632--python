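"""Quality filters and missing-value imputation for the minable dataset.

A reading is discarded when either channel is physiologically impossible
(systolic outside (70, 260) or diastolic outside (40, 150), strict bounds);
both channels come from one cuff inflation, so an impossible value on one
taints the pair.  Subjects retaining fewer than ``min_readings`` valid
readings are excluded.  Missing cholesterol is imputed deterministically
from an OLS regression on sex and age over complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ImputationError
from .io import ABPRecording

#: Strict validity bounds, mmHg: a reading survives iff low < value < high.
SBP_RANGE = (70.0, 260.0)
DBP_RANGE = (40.0, 150.0)
MIN_READINGS = 40


@dataclass
class QCReport:
    """Bookkeeping of what preprocessing did."""

    subjects_in: int = 0
    subjects_excluded_low_readings: int = 0
    readings_discarded_outlier: int = 0
    missing_imputed: int = 0
    #: missingness of the imputed attribute under two denominators (percent);
    #: the per-cell one divides by rows x attributes, the per-column one by rows.
    missing_percent_cells: float | None = None
    missing_percent_column: float | None = None

    @property
    def subjects_out(self) -> int:
        return self.subjects_in - self.subjects_excluded_low_readings

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subjects_out"] = self.subjects_out
        return d


def missing_percentage(n_missing: int, n_rows: int, n_attributes: int | None = None) -> float:
    """Percent of missing cells, rounded to one decimal.

    With ``n_attributes`` the denominator is the full rows x attributes grid;
    without it, a single column of length ``n_rows``.
    """
    denom = n_rows * n_attributes if n_attributes else n_rows
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * n_missing / denom, 1)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (matches clinical-report conventions)."""
    factor = 10.0 ** ndigits
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def filter_readings(
    rec: ABPRecording,
    sbp_range: tuple[float, float] = SBP_RANGE,
    dbp_range: tuple[float, float] = DBP_RANGE,
) -> ABPRecording:
    """Drop out-of-range readings, keeping original times and order.

    The discard inequalities are strict (a reading is an outlier only when
    it is strictly beyond a bound), so a systolic of exactly 260 or a
    diastolic of exactly 40 survives.  Idempotent by construction.
    """
    kept = tuple(
        r
        for r in rec.readings
        if sbp_range[0] <= r.systolic <= sbp_range[1]
        and dbp_range[0] <= r.diastolic <= dbp_range[1]
    )
    if len(kept) == len(rec.readings):
        return rec
    return ABPRecording(rec.subject_id, kept, rec.max_duration_min)


def qc_recording(rec: ABPRecording, min_readings: int = MIN_READINGS) -> bool:
    """Keep decision: True iff the recording has >= ``min_readings`` readings.

    Apply :func:`filter_readings` first; the count refers to valid readings.
    """
    return len(rec.readings) >= min_readings


def impute_missing(
    table: pd.DataFrame,
    attribute: str,
    report: QCReport | None = None,
) -> pd.DataFrame:
    """Fill missing cells of ``attribute`` from an OLS fit on (sex, age).

    The fit uses complete cases only; predictions replace missing cells;
    observed cells are never touched.  Deterministic: no stochastic residual
    is added.  Raises :class:`ImputationError` when fewer than four complete
    cases are available (predictors + 2).
    """
    missing = table[attribute].isna()
    n_missing = int(missing.sum())
    if report is not None:
        report.missing_imputed += n_missing
        report.missing_percent_cells = missing_percentage(
            n_missing, len(table), n_attributes=7
        )
        report.missing_percent_column = missing_percentage(n_missing, len(table))
    if n_missing == 0:
        return table

    complete = ~missing
    n_complete = int(complete.sum())
    if n_complete < 4:  # 2 predictors + 2
        raise ImputationError(
            f"cannot impute {attribute!r}: only {n_complete} complete cases"
        )
    if table.loc[complete, ["sex", "age"]].isna().any().any():
        raise ImputationError("sex and age must be complete to impute")

    X = np.column_stack(
        [
            np.ones(n_complete),
            table.loc[complete, "sex"].to_numpy(float),
            table.loc[complete, "age"].to_numpy(float),
        ]
    )
    y = table.loc[complete, attribute].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    Xm = np.column_stack(
        [
            np.ones(n_missing),
            table.loc[missing, "sex"].to_numpy(float),
            table.loc[missing, "age"].to_numpy(float),
        ]
    )
    out = table.copy()
    out.loc[missing, attribute] = Xm @ beta
    return out


def preprocess_recordings(
    recordings: list[ABPRecording],
    min_readings: int = MIN_READINGS,
    sbp_range: tuple[float, float] = SBP_RANGE,
    dbp_range: tuple[float, float] = DBP_RANGE,
    report: QCReport | None = None,
) -> list[ABPRecording]:
    """Filter readings then exclude low-count subjects; updates ``report``."""
    if report is None:
        report = QCReport()
    report.subjects_in += len(recordings)
    kept = []
    for rec in recordings:
        clean = filter_readings(rec, sbp_range, dbp_range)
        report.readings_discarded_outlier += len(rec.readings) - len(clean.readings)
        if qc_recording(clean, min_readings):
            kept.append(clean)
        else:
            report.subjects_excluded_low_readings += 1
    return kept
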