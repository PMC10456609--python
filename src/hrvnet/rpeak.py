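"""Hamilton-Tompkins R-peak detection and RR-interval extraction.

The detector follows the classic QRS pipeline: band-pass the ECG to the
QRS-dominant band, differentiate, rectify, integrate with a short moving
window, then walk the integrated-signal local maxima with an adaptive
peak/noise threshold. Detections are finally relocated to the nearest local
extremum of the input waveform so that RR intervals are accurate to one
sample.

Default constants (band 8-16 Hz, 80 ms integration window, threshold
coefficient 0.3125, estimate update weight 0.125, 200 ms refractory, 360 ms
T-wave window, search-back at half threshold beyond 1.5x the running RR
average) are the published parameterization of this detector family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import EcgRecord


class InsufficientDataError(ValueError):
    """Input too short for the requested operation."""


@dataclass
class RPeakAnnotation:
    """Detected R-peak sample indices at a given sampling rate."""

    peak_indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.peak_indices.size > 1 and np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.peak_indices / self.fs


@dataclass
class RRSeries:
    """Ordered inter-beat intervals in seconds.

    ``beat_times[i]`` is the absolute time of the beat terminating
    ``intervals[i]``, so ``intervals[i] = beat_times[i] - beat_times[i-1]``
    (with the series' implicit starting beat at ``beat_times[0] -
    intervals[0]``).
    """

    intervals: np.ndarray
    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.intervals.shape != self.beat_times.shape:
            raise ValueError("intervals and beat_times must align")
        if np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size


# detector constants
BAND_HZ = (8.0, 16.0)
INTEGRATION_S = 0.080
REFRACTORY_S = 0.200
TWAVE_WINDOW_S = 0.360
THRESH_COEF = 0.3125
UPDATE_W = 0.125
SEARCHBACK_FACTOR = 1.5
RELOCATE_S = 0.040


def _integrated_signal(x: np.ndarray, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(BAND_HZ[1], 0.9 * nyq)
    b, a = sps.butter(2, [BAND_HZ[0] / nyq, hi / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)
    deriv = np.gradient(bp)
    rect = np.abs(deriv)
    win = max(1, int(round(INTEGRATION_S * fs)))
    return sps.convolve(rect, np.ones(win) / win, mode="same")


def detect_rpeaks(record: EcgRecord) -> RPeakAnnotation:
    """Detect R-peaks with the Hamilton-Tompkins adaptive-threshold scheme.

    Returns an empty annotation on a flat record; raises
    :class:`InsufficientDataError` for records shorter than 10 s (the
    threshold-learning phase needs that much signal).
    """
    fs = record.fs
    x = record.samples
    if x.size / fs < 10.0:
        raise InsufficientDataError(
            f"record of {x.size / fs:.2f} s is shorter than the 10 s minimum")
    if np.ptp(x) == 0:
        return RPeakAnnotation(np.empty(0, dtype=np.int64), fs)

    integ = _integrated_signal(x, fs)
    refractory = int(round(REFRACTORY_S * fs))
    # -inf padding lets a maximum at either record boundary qualify as a
    # candidate (a beat can end flush with the record)
    padded = np.concatenate([[-np.inf], integ, [-np.inf]])
    cand_idx, _ = sps.find_peaks(padded, distance=refractory)
    cand_idx = cand_idx - 1
    if cand_idx.size == 0:
        return RPeakAnnotation(np.empty(0, dtype=np.int64), fs)
    cand_amp = integ[cand_idx]

    # learning phase: first two seconds seed the running estimates
    learn = integ[: int(2 * fs)]
    spki = float(np.max(learn))
    npki = float(np.mean(learn))

    qrs: list[int] = []
    qrs_slopes: list[float] = []
    rr_hist: list[float] = []

    def threshold() -> float:
        return npki + THRESH_COEF * (spki - npki)

    def accept(pos: int, amp: float) -> None:
        nonlocal spki
        spki = UPDATE_W * amp + (1 - UPDATE_W) * spki
        if qrs:
            rr_hist.append((pos - qrs[-1]) / fs)
            del rr_hist[:-8]
        qrs.append(pos)
        qrs_slopes.append(amp)

    for j in range(cand_idx.size):
        pos, amp = int(cand_idx[j]), float(cand_amp[j])
        if qrs and pos - qrs[-1] < refractory:
            continue
        is_qrs = amp > threshold()
        if (is_qrs and qrs
                and (pos - qrs[-1]) / fs < TWAVE_WINDOW_S
                and amp < 0.5 * qrs_slopes[-1]):
            is_qrs = False  # T wave: close to the previous QRS, low slope
        if is_qrs:
            accept(pos, amp)
        else:
            npki = UPDATE_W * amp + (1 - UPDATE_W) * npki
        # search-back when the gap exceeds 1.5x the running RR average
        if qrs and len(rr_hist) >= 1:
            rr_avg = float(np.mean(rr_hist))
            if (pos - qrs[-1]) / fs > SEARCHBACK_FACTOR * rr_avg:
                lo, hi = qrs[-1] + refractory, pos
                in_gap = (cand_idx > lo) & (cand_idx < hi)
                if np.any(in_gap):
                    gap_amp = np.where(in_gap, cand_amp, -np.inf)
                    best = int(np.argmax(gap_amp))
                    if cand_amp[best] > 0.5 * threshold():
                        accept(int(cand_idx[best]), float(cand_amp[best]))
                        qrs.sort()

    # relocate each detection to the raw-signal extremum within +/-40 ms
    half = int(round(RELOCATE_S * fs))
    relocated = []
    for pos in qrs:
        lo, hi = max(0, pos - half), min(x.size, pos + half + 1)
        relocated.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    relocated = sorted(set(relocated))
    # merging after relocation can re-introduce sub-refractory pairs; keep
    # the larger of any such pair
    cleaned: list[int] = []
    for pos in relocated:
        if cleaned and pos - cleaned[-1] < refractory:
            if np.abs(x[pos]) > np.abs(x[cleaned[-1]]):
                cleaned[-1] = pos
        else:
            cleaned.append(pos)
    return RPeakAnnotation(np.asarray(cleaned, dtype=np.int64), fs)


def to_rr(ann: RPeakAnnotation) -> RRSeries:
    """Convert a peak annotation to an RR-interval series (N peaks -> N-1)."""
    if ann.peak_indices.size < 2:
        raise InsufficientDataError(
            "at least two peaks are required to form RR intervals")
    times = ann.peak_indices / ann.fs
    return RRSeries(np.diff(times), times[1:])
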