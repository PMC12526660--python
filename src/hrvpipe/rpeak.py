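"""Pan–Tompkins-style R-peak detection for single-lead ECG.

Stages: zero-phase 5–15 Hz band-pass, derivative, squaring, 150 ms
moving-window integration, adaptive signal/noise thresholds with a 200 ms
refractory period and a search-back pass at half threshold for long gaps.
Each accepted fiducial is refined to the local raw-signal maximum within
±50 ms, with parabolic sub-sample interpolation of the peak time.

Detections are invariant to positive amplitude scaling and baseline
offset: the band-pass removes the offset and all thresholds are derived
from the processed signal itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .exceptions import InsufficientDataError, InvalidParameterError

logger = logging.getLogger(__name__)

BAND_HZ = (5.0, 15.0)           # QRS energy band
INTEGRATION_WINDOW_S = 0.150    # moving-average window
REFRACTORY_S = 0.200            # minimum physiological beat spacing
REFINE_WINDOW_S = 0.050         # raw-signal peak refinement half-window
SEARCHBACK_FACTOR = 1.66        # gap > factor * running mean RR triggers search-back


@dataclass(frozen=True)
class RPeakAnnotation:
    """Detected R-peak positions: integer sample indices plus sub-sample times."""

    indices: np.ndarray
    times_s: np.ndarray
    fs: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "times_s", t)
        if idx.size != t.size:
            raise InvalidParameterError("indices and times_s must be the same length")
        if t.size > 1:
            gaps = np.diff(t)
            if np.any(gaps <= 0):
                raise InvalidParameterError("R-peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)


def _integrated_envelope(signal: np.ndarray, fs: float) -> np.ndarray:
    sos = butter(2, BAND_HZ, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, signal)
    deriv = np.gradient(filtered)
    squared = deriv * deriv
    win = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    kernel = np.ones(win) / win
    return np.convolve(squared, kernel, mode="same")


def _refine_peak(signal: np.ndarray, center: int, fs: float) -> tuple[int, float]:
    """Local raw-signal maximum near ``center``, with parabolic sub-sample fit."""
    half = int(round(REFINE_WINDOW_S * fs))
    lo = max(0, center - half)
    hi = min(signal.size, center + half + 1)
    window = signal[lo:hi]
    # light [1,2,1] smoothing stabilizes the vertex under additive noise
    if window.size >= 3:
        smooth = np.convolve(window, np.array([0.25, 0.5, 0.25]), mode="same")
    else:
        smooth = window
    i0 = int(np.argmax(smooth))
    idx = lo + i0
    frac = 0.0
    if 0 < i0 < smooth.size - 1:
        y0, y1, y2 = smooth[i0 - 1], smooth[i0], smooth[i0 + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # proper maximum curvature
            frac = float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    return idx, (idx + frac) / fs


def detect(signal: np.ndarray, fs: float) -> RPeakAnnotation:
    """Detect R-peaks in a single-lead ECG trace.

    Parameters
    ----------
    signal : array of amplitudes (mV)
    fs : sampling rate in Hz (>= 100)

    Returns an empty annotation (with a logged warning) when no peak rises
    above threshold, so batch runs can skip flat or unusable records.
    """
    if fs < 100:
        raise InvalidParameterError(f"fs must be >= 100 Hz, got {fs}")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidParameterError("signal must be 1-d")
    if x.size < int(2 * fs):
        raise InsufficientDataError(
            f"signal too short: {x.size} samples < 2 s at {fs} Hz"
        )

    integ = _integrated_envelope(x, fs)
    refractory = int(round(REFRACTORY_S * fs))
    candidates, _ = find_peaks(integ, distance=max(1, refractory))
    if candidates.size == 0 or not np.any(integ > 0):
        logger.warning("no R-peak candidates above threshold; empty annotation")
        return RPeakAnnotation(np.array([], dtype=np.int64), np.array([]), fs)

    # adaptive signal/noise running estimates, initialized from the first 2 s
    head = integ[: int(2 * fs)]
    spki = 0.5 * float(head.max())
    npki = 0.5 * float(head.mean())
    threshold = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rejected: list[int] = []
    rr_history: list[float] = []

    for c in candidates:
        peak = integ[c]
        if peak > threshold:
            # search-back first: did we skip a beat in a long gap?
            if accepted and rr_history:
                rr_mean = float(np.mean(rr_history[-8:]))
                if (c - accepted[-1]) > SEARCHBACK_FACTOR * rr_mean:
                    gap = [
                        r
                        for r in rejected
                        if accepted[-1] + refractory < r < c - refractory
                        and integ[r] > 0.5 * threshold
                    ]
                    if gap:
                        best = max(gap, key=lambda r: integ[r])
                        rr_history.append(best - accepted[-1])
                        accepted.append(best)
            if accepted:
                rr_history.append(c - accepted[-1])
            accepted.append(c)
            spki = 0.125 * peak + 0.875 * spki
        else:
            rejected.append(c)
            npki = 0.125 * peak + 0.875 * npki
        threshold = npki + 0.25 * (spki - npki)

    if not accepted:
        logger.warning("no R-peak exceeded the adaptive threshold; empty annotation")
        return RPeakAnnotation(np.array([], dtype=np.int64), np.array([]), fs)

    refined = [_refine_peak(x, c, fs) for c in sorted(accepted)]
    # dedupe + enforce refractory after refinement, keeping the taller peak
    indices: list[int] = []
    times: list[float] = []
    for idx, t in refined:
        if indices and (t - times[-1]) < REFRACTORY_S:
            if x[idx] > x[indices[-1]]:
                indices[-1], times[-1] = idx, t
            continue
        indices.append(idx)
        times.append(t)
    return RPeakAnnotation(np.array(indices, dtype=np.int64), np.array(times), fs)


def evaluate(
    pred: RPeakAnnotation | np.ndarray,
    truth_times_s: np.ndarray,
    tol_ms: float = 40.0,
) -> dict[str, float]:
    """Recall/precision of detections against ground-truth R times.

    Greedy one-to-one matching in time order: walking both sorted event
    lists, a prediction and a truth event within ``tol_ms`` of each other
    are matched and both consumed.
    """
    if tol_ms <= 0:
        raise InvalidParameterError("tol_ms must be positive")
    p = np.asarray(pred.times_s if isinstance(pred, RPeakAnnotation) else pred, float)
    t = np.asarray(truth_times_s, dtype=float)
    tol = tol_ms / 1000.0
    i = j = matches = 0
    while i < p.size and j < t.size:
        dt = p[i] - t[j]
        if abs(dt) <= tol:
            matches += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    recall = matches / t.size if t.size else 0.0
    precision = matches / p.size if p.size else 0.0
    return {"recall": recall, "precision": precision}
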