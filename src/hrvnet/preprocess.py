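"""Wavelet denoising and amplitude normalization for ECG records.

Denoising uses a discrete wavelet transform (sym5 by default): the
decomposition level is chosen so the approximation band sits below 0.5 Hz,
the approximation coefficients are zeroed to remove baseline wander, and
the two finest detail levels are soft-thresholded with the universal
threshold sigma*sqrt(2*ln n), sigma estimated as median(|d1|)/0.6745, to
suppress wideband noise. Symmetric signal extension avoids edge artifacts
that could mimic QRS complexes.

Normalization offers two scale-invariant schemes:

* NADev  — center on the mean, divide by the mean absolute deviation;
* NADiff — center on the mean, divide by the mean absolute successive
  difference.

Both leave the output mean at zero and the respective denominator of the
output equal to one, so detector thresholds transfer across records.
"""

from __future__ import annotations

import math

import numpy as np
import pywt

from .io import EcgRecord

DEFAULT_WAVELET = "sym5"
BASELINE_CUTOFF_HZ = 0.5
N_THRESHOLDED_DETAILS = 2


class DegenerateInputError(ValueError):
    """Signal is constant (or too short) for the requested normalization."""


def baseline_level(fs: float, cutoff_hz: float = BASELINE_CUTOFF_HZ) -> int:
    """Smallest decomposition level whose approximation band is below cutoff."""
    return max(1, math.ceil(math.log2(fs / cutoff_hz)) - 1)


def denoise_dwt(record: EcgRecord, wavelet_name: str = DEFAULT_WAVELET,
                level: int | None = None) -> EcgRecord:
    """Remove baseline wander and wideband noise by wavelet decomposition.

    Output length equals input length. Raises ``ValueError`` when the
    record is too short for the requested level.
    """
    x = record.samples
    wavelet = pywt.Wavelet(wavelet_name)
    if level is None:
        level = baseline_level(record.fs)
        level = min(level, pywt.dwt_max_level(x.size, wavelet.dec_len))
    if x.size < 2 ** level:
        raise ValueError(
            f"record of {x.size} samples too short for level {level}")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="symmetric")
    coeffs[0] = np.zeros_like(coeffs[0])  # kill the sub-cutoff approximation
    d1 = coeffs[-1]
    sigma = float(np.median(np.abs(d1))) / 0.6745
    if sigma > 0:
        thr = sigma * math.sqrt(2.0 * math.log(x.size))
        for j in range(1, N_THRESHOLDED_DETAILS + 1):
            if j <= len(coeffs) - 1:
                coeffs[-j] = pywt.threshold(coeffs[-j], thr, mode="soft")
    y = pywt.waverec(coeffs, wavelet, mode="symmetric")[: x.size]
    return record.with_samples(y)


def normalize(record: EcgRecord, method: str = "NADev") -> EcgRecord:
    """Normalize amplitude by mean absolute deviation or difference.

    NADev: ``y = (x - mean(x)) / mean(|x - mean(x)|)``;
    NADiff: ``y = (x - mean(x)) / mean(|x_i - x_{i-1}|)``.
    """
    x = record.samples
    centered = x - np.mean(x)
    if method == "NADev":
        denom = float(np.mean(np.abs(centered)))
    elif method == "NADiff":
        if x.size < 2:
            raise DegenerateInputError("NADiff needs at least two samples")
        denom = float(np.mean(np.abs(np.diff(x))))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if denom == 0:
        raise DegenerateInputError(
            f"constant signal: {method} denominator is zero")
    return record.with_samples(centered / denom)


def preprocess(record: EcgRecord, wavelet_name: str = DEFAULT_WAVELET,
               level: int | None = None, method: str = "NADev") -> EcgRecord:
    """Standard conditioning chain: denoise, then normalize."""
    return normalize(denoise_dwt(record, wavelet_name, level), method)
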