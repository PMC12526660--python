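"""Time-domain HRV features from R-peak annotations.

Three features are computed per record: RMSSD (root mean square of
successive RR-interval differences, the short-term parasympathetic HRV
index), mean heart rate, and the raw R-peak count. Intervals are handled
internally in milliseconds; the tabular feature surface stores RMSSD in
seconds (see :func:`feature_table`), matching the convention used for
cohort-level summary statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .rpeak import RPeakAnnotation, detect

if TYPE_CHECKING:  # pragma: no cover
    from .ecg_io import ECGRecord

logger = logging.getLogger(__name__)

#: minimum number of detected R-peaks for a record to yield features
MIN_PEAKS = 3


@dataclass(frozen=True)
class RRSeries:
    """Successive R-to-R intervals in milliseconds."""

    intervals_ms: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals_ms, dtype=float)
        object.__setattr__(self, "intervals_ms", arr)
        if arr.ndim != 1:
            raise InsufficientDataError("RR intervals must be a 1-d sequence")
        if arr.size and np.any(arr <= 0):
            raise InsufficientDataError("all RR intervals must be positive")

    def __len__(self) -> int:
        return int(self.intervals_ms.size)


@dataclass(frozen=True)
class HRVFeatures:
    """Per-record feature triple."""

    rmssd_ms: float
    mean_hr_bpm: float
    r_peak_count: int


def rr_from_peaks(peaks: RPeakAnnotation) -> RRSeries:
    """Convert R-peak times to successive RR intervals in milliseconds."""
    times = np.asarray(peaks.times_s, dtype=float)
    if times.size < 2:
        raise InsufficientDataError(
            f"need >= 2 R-peaks to form RR intervals, got {times.size}"
        )
    return RRSeries(np.diff(times) * 1000.0)


def rmssd(rr: RRSeries | Sequence[float]) -> float:
    """Root mean square of successive RR-interval differences, in ms.

    rmssd = sqrt( mean( (rr[i+1] - rr[i])^2 ) ). Translation-invariant and
    linear under rescaling of the intervals.
    """
    intervals = rr.intervals_ms if isinstance(rr, RRSeries) else np.asarray(rr, float)
    if intervals.size < 2:
        raise InsufficientDataError(
            f"need >= 2 RR intervals for RMSSD, got {intervals.size}"
        )
    diffs = np.diff(intervals)
    return float(np.sqrt(np.mean(diffs * diffs)))


def mean_heart_rate(rr: RRSeries | Sequence[float]) -> float:
    """Mean heart rate in beats per minute: 60000 / mean RR (ms)."""
    intervals = rr.intervals_ms if isinstance(rr, RRSeries) else np.asarray(rr, float)
    if intervals.size < 1:
        raise InsufficientDataError("empty RR series has no mean heart rate")
    return float(60000.0 / np.mean(intervals))


def features_from_record(record: "ECGRecord") -> HRVFeatures:
    """Detect R-peaks in one record and derive the three HRV features.

    Raises :class:`InsufficientDataError` when fewer than ``MIN_PEAKS``
    peaks are found; batch callers catch this and flag the record instead
    of aborting.
    """
    peaks = detect(record.signal, record.fs)
    if len(peaks) < MIN_PEAKS:
        raise InsufficientDataError(
            f"record {record.record_id}: {len(peaks)} R-peaks detected "
            f"(minimum {MIN_PEAKS})"
        )
    rr = rr_from_peaks(peaks)
    return HRVFeatures(
        rmssd_ms=rmssd(rr),
        mean_hr_bpm=mean_heart_rate(rr),
        r_peak_count=len(peaks),
    )


#: canonical column order of the per-record feature table
FEATURE_COLUMNS = ["record_id", "age", "sex", "site_id", "rmssd", "mean_hr", "r_peaks"]


def feature_row(record: "ECGRecord", feats: HRVFeatures) -> dict:
    """One feature-table row; ``rmssd`` is stored in seconds."""
    return {
        "record_id": record.record_id,
        "age": record.age,
        "sex": record.sex_code,
        "site_id": record.site_id,
        "rmssd": feats.rmssd_ms / 1000.0,
        "mean_hr": feats.mean_hr_bpm,
        "r_peaks": feats.r_peak_count,
    }


def feature_table(records: Iterable["ECGRecord"]) -> tuple[pd.DataFrame, list[str]]:
    """Feature rows for a batch of records.

    Records with too few detections (flat/undetectable signals) are
    excluded with a logged warning; their ids are returned alongside the
    table.
    """
    rows: list[dict] = []
    excluded: list[str] = []
    for record in records:
        try:
            feats = features_from_record(record)
        except InsufficientDataError as exc:
            logger.warning("excluding record: %s", exc)
            excluded.append(record.record_id)
            continue
        rows.append(feature_row(record, feats))
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    logger.info("feature extraction: %d records in, %d excluded", len(rows) + len(excluded), len(excluded))
    return table, excluded
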