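"""24-hour BP level (WBP) and Average Real Variability (ARV) per channel.

Both indices weight by the elapsed time between successive valid readings,
so they are invariant to uniform time rescaling and to shifting the clock.
With weights ``w_k = t_k - t_{k-1}`` over readings ``x_0..x_{n-1}``:

* ``ARV = sum(w_k * |x_k - x_{k-1}|) / sum(w_k)``
* ``WBP = sum(w_k * (x_k + x_{k-1}) / 2) / sum(w_k)`` (trapezoidal
  convention; the asymmetric "weight each reading by its preceding
  interval" convention is available as ``convention="right"``).

Gaps left by discarded readings are bridged: ``w_k`` spans the actual
elapsed time between surviving neighbours, with no cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import UndefinedIndexError, ValidationError
from .io import ABPRecording

WBP_CONVENTIONS = ("trapezoid", "right")


@dataclass(frozen=True)
class ChannelSeries:
    """One channel (systolic or diastolic) of an ABP recording."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)
        if values.shape != times.shape or values.ndim != 1:
            raise ValidationError("values and times must be 1-D and equal length")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IndexResult:
    wbp: float
    arv: float
    n_readings: int


@dataclass(frozen=True)
class RecordingIndices:
    """Per-recording summary: systolic/diastolic WBP and ARV, optional HR mean."""

    subject_id: str
    sbp: IndexResult
    dbp: IndexResult
    hr_mean: float | None
    n_readings: int


def _weights(series: ChannelSeries) -> np.ndarray:
    if len(series) < 2:
        raise UndefinedIndexError(
            f"index undefined for n={len(series)} readings (need >= 2)"
        )
    return np.diff(series.times)


def compute_arv(series: ChannelSeries) -> float:
    """Time-weighted mean absolute successive difference (mmHg)."""
    w = _weights(series)
    return float(np.sum(w * np.abs(np.diff(series.values))) / np.sum(w))


def compute_wbp(series: ChannelSeries, convention: str = "trapezoid") -> float:
    """Time-weighted mean BP level (mmHg).

    ``trapezoid`` weights the midpoint of each consecutive pair by the
    interval between them; ``right`` weights each reading (except the first)
    by its preceding interval.
    """
    w = _weights(series)
    x = series.values
    if convention == "trapezoid":
        return float(np.sum(w * (x[1:] + x[:-1]) / 2.0) / np.sum(w))
    if convention == "right":
        return float(np.sum(w * x[1:]) / np.sum(w))
    raise ValueError(f"unknown WBP convention {convention!r}")


def compute_indices(rec: ABPRecording, convention: str = "trapezoid") -> RecordingIndices:
    """WBP and ARV for both channels, plus a time-weighted heart-rate mean."""
    times = rec.times
    sbp = ChannelSeries(rec.systolic, times)
    dbp = ChannelSeries(rec.diastolic, times)
    hr = rec.heart_rate
    hr_mean = (
        compute_wbp(ChannelSeries(hr, times), convention) if hr is not None else None
    )
    return RecordingIndices(
        subject_id=rec.subject_id,
        sbp=IndexResult(compute_wbp(sbp, convention), compute_arv(sbp), len(rec)),
        dbp=IndexResult(compute_wbp(dbp, convention), compute_arv(dbp), len(rec)),
        hr_mean=hr_mean,
        n_readings=len(rec),
    )


def indices_table(recordings, convention: str = "trapezoid"):
    """DataFrame of per-subject indices: id, sbp_wbp, sbp_arv, dbp_wbp, dbp_arv, hr_mean, n_readings."""
    import pandas as pd

    rows = []
    for rec in recordings:
        ix = compute_indices(rec, convention)
        rows.append(
            {
                "id": ix.subject_id,
                "sbp_wbp": ix.sbp.wbp,
                "sbp_arv": ix.sbp.arv,
                "dbp_wbp": ix.dbp.wbp,
                "dbp_arv": ix.dbp.arv,
                "hr_mean": ix.hr_mean,
                "n_readings": ix.n_readings,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "sbp_wbp", "sbp_arv", "dbp_wbp", "dbp_arv", "hr_mean", "n_readings"],
    )
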