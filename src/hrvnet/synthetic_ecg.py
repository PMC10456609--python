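"""Synthetic ECG cohort generator with known ground truth.

The generator emulates the study design this package analyzes: five rhythm
classes (NSR, CAD, CHF, VT, SCD), 30-minute single-channel recordings, and
a cohort of 115 subjects split 18/51/15/11/20 across the classes.

RR intervals follow a truncated Gaussian AR(1) process

    RR_i = mu + phi * (RR_{i-1} - mu) + eps_i,   eps_i ~ N(0, sigma_eps^2)

with ``sigma_eps = sd_rr * sqrt(1 - phi^2)`` so that ``sd_rr`` is the
stationary standard deviation. The two parameters map analytically onto the
time-domain HRV statistics (SDRR -> sd_rr, RMSSD -> sd_rr*sqrt(2*(1-phi))),
which makes parameter-recovery testing possible. An optional per-beat
ectopic mechanism replaces an interval with a shortened one to inject
NN50-type events.

The ECG waveform is one P-QRS-T template per beat — five Gaussian bumps
with a dominant R wave — plus sinusoidal baseline wander, white noise and
powerline interference. The default class profiles are chosen to be
mutually separable in the eight-feature HRV space; they make no
physiological claim and do not reproduce real arrhythmia morphology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .io import CLASS_LABELS, EcgRecord
from .rpeak import RRSeries

DEFAULT_COHORT_SIZES: Dict[str, int] = {
    "NSR": 18, "CAD": 51, "CHF": 15, "VT": 11, "SCD": 20,
}
DEFAULT_DURATION_S = 1800.0
DEFAULT_FS = 128.0


class ProfileValidationError(ValueError):
    """A class profile violates one of its invariants."""


@dataclass(frozen=True)
class ClassProfile:
    """RR-process parameters for one rhythm class.

    mean_rr and sd_rr are the stationary mean/SD in seconds, phi the AR(1)
    coefficient, ectopic_rate the per-beat probability of a shortened
    ectopic-like interval, rr_bounds the truncation range in seconds.
    """

    label: str
    mean_rr: float
    sd_rr: float
    phi: float = 0.0
    ectopic_rate: float = 0.0
    rr_bounds: Tuple[float, float] = (0.25, 2.5)

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ProfileValidationError(f"unknown label {self.label!r}")
        if not self.mean_rr > 0:
            raise ProfileValidationError("mean_rr must be positive")
        if self.sd_rr < 0:
            raise ProfileValidationError("sd_rr must be non-negative")
        if not abs(self.phi) < 1:
            raise ProfileValidationError("|phi| must be < 1")
        if not 0 <= self.ectopic_rate <= 1:
            raise ProfileValidationError("ectopic_rate must lie in [0, 1]")
        lo, hi = self.rr_bounds
        if not lo < self.mean_rr < hi:
            raise ProfileValidationError(
                f"rr_bounds {self.rr_bounds} must bracket mean_rr {self.mean_rr}")


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: amplitude (mV), center offset (fraction of the
    local beat interval) and width (s)."""

    amplitude: float
    offset: float
    width: float


@dataclass(frozen=True)
class BeatTemplate:
    """P-QRS-T morphology as five Gaussian components."""

    p: WaveComponent = WaveComponent(0.12, -0.22, 0.025)
    q: WaveComponent = WaveComponent(-0.15, -0.03, 0.010)
    r: WaveComponent = WaveComponent(1.00, 0.00, 0.012)
    s: WaveComponent = WaveComponent(-0.25, 0.03, 0.010)
    t: WaveComponent = WaveComponent(0.30, 0.25, 0.060)

    def __post_init__(self) -> None:
        comps = self.components
        if any(c.width <= 0 for c in comps):
            raise ProfileValidationError("wave widths must be positive")
        others = [abs(c.amplitude) for c in (self.p, self.q, self.s, self.t)]
        if not abs(self.r.amplitude) > max(others):
            raise ProfileValidationError(
                "R amplitude must be strictly largest in absolute value")

    @property
    def components(self) -> Tuple[WaveComponent, ...]:
        return (self.p, self.q, self.r, self.s, self.t)

    @property
    def min_width(self) -> float:
        return min(c.width for c in self.components)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances: baseline wander, white noise, powerline hum."""

    baseline_amp: float = 0.2
    baseline_freq: float = 0.25
    white_sd: float = 0.05
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.white_sd, self.powerline_amp) < 0:
            raise ProfileValidationError("noise amplitudes must be >= 0")
        if not 0 < self.baseline_freq < 0.5:
            raise ProfileValidationError("baseline_freq must lie in (0, 0.5) Hz")
        if self.powerline_freq not in (50.0, 60.0):
            raise ProfileValidationError("powerline_freq must be 50 or 60 Hz")


ZERO_NOISE = NoiseSpec(0.0, 0.25, 0.0, 0.0, 50.0)

#: default per-class RR-process profiles, chosen for mutual separability in
#: (MRR, SDRR, RMSSD) space — not calibrated to any clinical population
DEFAULT_PROFILES: Dict[str, ClassProfile] = {
    "NSR": ClassProfile("NSR", mean_rr=0.85, sd_rr=0.050, phi=0.30),
    "CAD": ClassProfile("CAD", mean_rr=1.05, sd_rr=0.030, phi=0.50,
                        ectopic_rate=0.02),
    "CHF": ClassProfile("CHF", mean_rr=0.70, sd_rr=0.015, phi=0.20),
    "VT": ClassProfile("VT", mean_rr=0.45, sd_rr=0.020, phi=0.10,
                       ectopic_rate=0.05),
    "SCD": ClassProfile("SCD", mean_rr=0.60, sd_rr=0.080, phi=0.60,
                        ectopic_rate=0.08),
}


def generate_rr(profile: ClassProfile, duration: float, seed: int) -> RRSeries:
    """Draw a truncated Gaussian AR(1) RR series filling ``duration`` seconds.

    The series is the longest prefix whose cumulative sum does not exceed
    ``duration``. Identical arguments yield identical output.
    """
    if not duration > profile.mean_rr:
        raise ValueError("duration must exceed one mean RR interval")
    rng = np.random.default_rng(seed)
    mu, sd, phi = profile.mean_rr, profile.sd_rr, profile.phi
    lo, hi = profile.rr_bounds
    sigma_eps = sd * math.sqrt(1.0 - phi * phi)
    # generous draw: expected count + 6 sigma margin
    n_max = int(duration / max(lo, 1e-6)) + 2
    intervals = np.empty(n_max)
    prev = float(np.clip(rng.normal(mu, sd) if sd > 0 else mu, lo, hi))
    total = 0.0
    n = 0
    while True:
        rr = prev
        if profile.ectopic_rate > 0 and rng.random() < profile.ectopic_rate:
            rr = 0.55 * mu * (1.0 + 0.05 * rng.standard_normal())
        rr = float(np.clip(rr, lo, hi))
        if total + rr > duration:
            break
        intervals[n] = rr
        total += rr
        n += 1
        prev = mu + phi * (prev - mu) + (sigma_eps * rng.standard_normal()
                                         if sigma_eps > 0 else 0.0)
        prev = float(np.clip(prev, lo, hi))
    ivals = intervals[:n].copy()
    return RRSeries(ivals, np.cumsum(ivals))


def synthesize_ecg(rr: RRSeries, fs: float, template: BeatTemplate = BeatTemplate(),
                   noise: NoiseSpec = ZERO_NOISE, seed: int = 0, *,
                   duration: Optional[float] = None,
                   subject_id: str = "synthetic", label: Optional[str] = None,
                   ) -> EcgRecord:
    """Render an ECG waveform from an RR series.

    One template instance is centered at each beat time (beats at 0 and at
    each cumulative interval sum, so N intervals produce N+1 ground-truth
    peaks). Noise terms are added per ``noise`` with phases/samples drawn
    from ``seed``.
    """
    if fs < 100:
        raise ValueError(f"fs={fs} Hz is too low; at least 100 Hz required")
    if template.min_width * fs < 1.0:
        raise ValueError(
            f"fs={fs} Hz cannot resolve template width {template.min_width} s")
    beat_times = np.concatenate([[0.0], rr.beat_times])
    # render past the final R so its S/T waves are not cut off
    last_rr = rr.intervals[-1] if len(rr) else 1.0
    tail = max(c.offset * last_rr + 4.0 * c.width
               for c in template.components)
    n_samples = int(round((beat_times[-1] + max(0.0, tail)) * fs)) + 1
    if duration is not None:
        n_samples = max(n_samples, int(round(duration * fs)))
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    # local beat interval scales the P/T offsets of each beat
    local_rr = np.empty(beat_times.size)
    local_rr[1:] = rr.intervals
    local_rr[0] = rr.intervals[0] if len(rr) else 1.0
    for bt, lrr in zip(beat_times, local_rr):
        for comp in template.components:
            center = bt + comp.offset * lrr
            half = 4.0 * comp.width
            lo = max(0, int(math.floor((center - half) * fs)))
            hi = min(n_samples, int(math.ceil((center + half) * fs)) + 1)
            if hi <= lo:
                continue
            tt = t[lo:hi] - center
            x[lo:hi] += comp.amplitude * np.exp(-0.5 * (tt / comp.width) ** 2)
    rng = np.random.default_rng(seed)
    if noise.baseline_amp > 0:
        x += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        x += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.white_sd > 0:
        x += noise.white_sd * rng.standard_normal(n_samples)
    peaks = np.round(beat_times * fs).astype(np.int64)
    return EcgRecord(x, fs, subject_id=subject_id, label=label,
                     source="synthetic", ground_truth_peaks=peaks)


def record_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-record seed: SeedSequence of (master, index)."""
    return int(np.random.SeedSequence((master_seed, subject_index))
               .generate_state(1)[0] % (2 ** 31))


def generate_cohort(profiles: Optional[Dict[str, ClassProfile]] = None,
                    sizes: Optional[Dict[str, int]] = None,
                    duration: float = DEFAULT_DURATION_S,
                    fs: float = DEFAULT_FS,
                    seed: int = 0,
                    template: BeatTemplate = BeatTemplate(),
                    noise: NoiseSpec = NoiseSpec(),
                    ) -> list[EcgRecord]:
    """Generate the full labeled cohort (default 18/51/15/11/20 = 115).

    Subject order follows ``CLASS_LABELS``; per-record seeds derive from the
    master seed via :func:`record_seed`, so regeneration with the same seed
    reproduces the cohort exactly.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    sizes = dict(DEFAULT_COHORT_SIZES if sizes is None else sizes)
    if any(n < 1 for n in sizes.values()):
        raise ValueError("each requested class needs size >= 1")
    records: list[EcgRecord] = []
    idx = 0
    for label in CLASS_LABELS:
        if label not in sizes:
            continue
        prof = profiles[label]
        for k in range(sizes[label]):
            s = record_seed(seed, idx)
            rr = generate_rr(prof, duration, s)
            rec = synthesize_ecg(
                rr, fs, template=template, noise=noise, seed=s + 1,
                duration=duration,
                subject_id=f"{label.lower()}{k + 1:03d}", label=label)
            records.append(rec)
            idx += 1
    return records
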