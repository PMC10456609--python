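"""Five-minute segmentation and time-domain HRV statistics.

Eight statistics are computed per RR series, matching the conventions this
pipeline standardizes on:

* MRR    — mean RR interval (s)
* SDRR   — population standard deviation, 1/N normalization (s)
* RMSSD  — root mean square of successive differences, 1/(N-1) (s)
* PNN50  — fraction of successive differences strictly exceeding 50 ms,
           with denominator N (the interval count, not the difference count)
* CVRR   — SDRR / MRR (dimensionless)
* NN50   — count of successive differences >= 50 ms
* Min_RR, Max_RR — extrema (s)

Note the deliberate asymmetry: NN50 uses ">=" while PNN50 uses a strict
">", and PNN50 divides by N rather than N-1. Both comparators and the
PNN50 denominator are configurable; the defaults follow the definitions
above. The differences only matter for successive differences tied at
exactly 50 ms, and for PNN50 by a factor (N-1)/N.

The classifier input vector is the eight statistics plus the interval
count N, in the fixed order (MRR, SDRR, RMSSD, PNN50, CVRR, NN50, Min_RR,
Max_RR, N).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .io import FEATURE_COLUMNS
from .rpeak import InsufficientDataError, RRSeries

NN50_THRESHOLD_S = 0.050
SEGMENT_WINDOW_S = 300.0


@dataclass(frozen=True)
class HrvFeatures:
    """Time-domain HRV statistics of one RR series."""

    MRR: float
    SDRR: float
    RMSSD: float
    PNN50: float
    CVRR: float
    NN50: int
    Min_RR: float
    Max_RR: float
    N: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FEATURE_COLUMNS}


@dataclass
class Segment:
    """One analysis window of a subject's RR series."""

    subject_id: str
    segment_index: int  # 1-based
    t0: float
    t1: float
    rr: RRSeries


def segment_record(rr: RRSeries, duration: float,
                   window: float = SEGMENT_WINDOW_S, *,
                   subject_id: str = "") -> List[Segment]:
    """Split an RR series into consecutive fixed windows.

    An interval belongs to the window containing its terminating beat
    time; windows are half-open ``[t0, t0 + window)`` except the last,
    which also keeps a beat landing exactly on the record end. A trailing
    partial window is dropped.
    """
    if duration < window:
        raise ValueError(
            f"duration {duration} s shorter than the window {window} s")
    n_seg = int(duration // window)
    segments = []
    for k in range(n_seg):
        t0, t1 = k * window, (k + 1) * window
        if k == n_seg - 1:
            mask = (rr.beat_times >= t0) & (rr.beat_times <= t1)
        else:
            mask = (rr.beat_times >= t0) & (rr.beat_times < t1)
        sub = RRSeries(rr.intervals[mask], rr.beat_times[mask])
        segments.append(Segment(subject_id, k + 1, t0, t1, sub))
    return segments


def compute_features(rr: RRSeries, *, pnn50_strict: bool = True,
                     nn50_strict: bool = False,
                     pnn50_denominator: str = "N") -> HrvFeatures:
    """Compute the eight time-domain statistics of an RR series.

    Requires at least two intervals. ``pnn50_strict``/``nn50_strict``
    select ">" versus ">=" against the 50 ms threshold;
    ``pnn50_denominator`` is ``"N"`` or ``"N-1"``.
    """
    x = rr.intervals
    n = x.size
    if n < 2:
        raise InsufficientDataError(
            f"need at least 2 RR intervals, got {n}")
    mrr = float(np.mean(x))
    sdrr = float(np.sqrt(np.mean((x - mrr) ** 2)))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.sum(d ** 2) / (n - 1)))
    nn50_cmp = np.abs(d) > NN50_THRESHOLD_S if nn50_strict \
        else np.abs(d) >= NN50_THRESHOLD_S
    pnn_cmp = np.abs(d) > NN50_THRESHOLD_S if pnn50_strict \
        else np.abs(d) >= NN50_THRESHOLD_S
    denom = n if pnn50_denominator == "N" else n - 1
    return HrvFeatures(
        MRR=mrr,
        SDRR=sdrr,
        RMSSD=rmssd,
        PNN50=float(np.count_nonzero(pnn_cmp)) / denom,
        CVRR=sdrr / mrr,
        NN50=int(np.count_nonzero(nn50_cmp)),
        Min_RR=float(np.min(x)),
        Max_RR=float(np.max(x)),
        N=int(n),
    )


def to_input_vector(f: HrvFeatures) -> np.ndarray:
    """Fixed-order length-9 classifier input:
    (MRR, SDRR, RMSSD, PNN50, CVRR, NN50, Min_RR, Max_RR, N)."""
    return np.array([f.MRR, f.SDRR, f.RMSSD, f.PNN50, f.CVRR,
                     float(f.NN50), f.Min_RR, f.Max_RR, float(f.N)])


class FeatureStandardizer:
    """Per-column standardization fitted on training rows only."""

    def __init__(self) -> None:
        self.mean_: Optional[np.ndarray] = None
        self.scale_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "FeatureStandardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant columns pass through centered
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("standardizer not fitted")
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def feature_rows_for_record(rr: RRSeries, duration: float, subject_id: str,
                            label: Optional[str],
                            window: float = SEGMENT_WINDOW_S) -> List[dict]:
    """Per-segment feature-table rows (see ``io.write_feature_table``)."""
    rows = []
    for seg in segment_record(rr, duration, window, subject_id=subject_id):
        feats = compute_features(seg.rr)
        row = {"subject_id": subject_id, "segment": seg.segment_index,
               "label": label}
        row.update(feats.as_dict())
        rows.append(row)
    return rows
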