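# Methods

## Scope and data model

The package analyzes single-channel ECG at the subject level: a recording
(nominally 30 minutes) is conditioned, R-peaks are detected, the RR
tachogram is split into 5-minute windows, eight time-domain HRV statistics
plus the interval count are computed per window, and a five-class
classifier (NSR, CAD, CHF, VT, SCD) is trained and evaluated on those
length-9 vectors. Real recordings can be supplied as WFDB records (formats
212 and 16) or two-column CSV; all development and testing runs on the
built-in synthetic cohort, whose ground truth makes every stage falsifiable.

## Synthetic RR process

RR intervals follow a truncated Gaussian AR(1) process

    RR_i = μ + φ (RR_{i−1} − μ) + ε_i,   ε_i ~ N(0, σ_ε²),
    σ_ε = sd_rr · √(1 − φ²),

truncated to `rr_bounds` (default 0.25–2.5 s). Under this parameterization
`sd_rr` is the stationary standard deviation, so the statistics the
pipeline computes have closed forms: SDRR → sd_rr, RMSSD →
sd_rr·√(2(1−φ)). That analytic map is what the parameter-recovery tests
assert (±1 % on the mean, ±5 % on SDRR/RMSSD at N = 10⁴, tolerances set by
Monte-Carlo error at that sample size). An optional ectopic mechanism
replaces a beat's interval, with probability `ectopic_rate`, by
0.55·μ·(1 + 0.05·N(0,1)) — a crude surrogate for premature beats that
injects NN50-type events and inflates dispersion.

A series is the longest prefix of draws whose cumulative sum stays within
the requested duration; the terminating beat of each interval carries its
absolute time, and the waveform renderer places one template per beat
(beats at t = 0 and at each cumulative sum, so N intervals give N + 1
ground-truth peaks).

### Default class profiles

| class | μ (s) | sd_rr (s) | φ | ectopic rate |
|---|---|---|---|---|
| NSR | 0.85 | 0.050 | 0.30 | 0 |
| CAD | 1.05 | 0.030 | 0.50 | 0.02 |
| CHF | 0.70 | 0.015 | 0.20 | 0 |
| VT  | 0.45 | 0.020 | 0.10 | 0.05 |
| SCD | 0.60 | 0.080 | 0.60 | 0.08 |

These were fixed once, before any classifier runs, to be mutually
separable in (MRR, SDRR, RMSSD) space — distinct means, and distinct
dispersion where means are close. They are *not* calibrated to clinical
populations and make no physiological claim (real VT is not merely "fast
with small variance"; real SCD precursors are not merely "variable"). The
published per-class feature tables for the corresponding clinical groups
contain internally implausible values (fractional beat counts, minimum RR
of 7 ms), so no attempt was made to match them numerically.

Default cohort: 18 NSR / 51 CAD / 15 CHF / 11 VT / 20 SCD = 115 subjects,
1800 s per record. The cohort sampling rate defaults to 128 Hz, chosen as
the package's desk-scale default (the QRS detection band tops out at 16 Hz,
so 128 Hz leaves ample margin); any fs ≥ 100 Hz may be passed. Per-record
seeds derive from the master seed via `SeedSequence((master, index))`, so a
cohort is reproducible record-by-record.

### Waveform and noise

Each beat is five Gaussian bumps (P, Q, R, S, T) with amplitudes in mV,
widths in seconds, and centers offset by a fraction of the local RR
interval; the default template has a dominant 1.0 mV R wave. The record is
rendered past the final R peak so its S/T waves are complete, and, when an
explicit duration is given, padded to that length. Noise is additive:
sinusoidal baseline wander (default 0.2 mV at 0.25 Hz), white Gaussian
noise (0.05 mV), and powerline hum (0.02 mV at 50 Hz), each with seeded
phase/samples.

What the generator does **not** emulate: multi-lead geometry, morphology
changes (bundle-branch block, VF waveforms, bigeminy), non-stationary
rhythm transitions, muscle artifact, electrode motion spikes. Passing
tests therefore demonstrate correctness of the pipeline's arithmetic and
its robustness to stationary additive noise — not clinical performance.

## Preprocessing

Denoising decomposes the signal with the sym5 wavelet (symmetric
extension, to avoid edge spikes that mimic QRS). The decomposition level
is the smallest L whose approximation band lies below 0.5 Hz
(L = ⌈log₂(fs/0.5)⌉ − 1, capped by the signal length); the approximation
is zeroed, removing baseline wander. The two finest detail levels are
soft-thresholded with the universal threshold σ√(2 ln n),
σ = median(|d₁|)/0.6745. Verified behavior on synthetic fixtures: ≥ 20 dB
attenuation below 0.5 Hz, ≤ 3 dB change in the 8–16 Hz QRS band, ≥ 0.99
correlation with a clean constant-rate input, < 1 % RMS change on
reapplication. Note that zeroing the sub-0.5 Hz band necessarily also
removes genuine slow heart-rate modulation of the signal's local mean;
on strongly rate-modulated records the clean-signal correlation dips just
below 0.99, which is inherent to any baseline-removal scheme with this
cutoff.

Normalization offers NADev, y = (x − x̄)/mean(|x − x̄|), and NADiff,
y = (x − x̄)/mean(|xᵢ − xᵢ₋₁|). The source description names both
techniques without printing formulas; these centering + mean-absolute-scale
definitions were adopted for their affine invariance, which lets detector
thresholds transfer across records. NADev is the default and the two are
alternatives, not a sequence.

## R-peak detection

Hamilton–Tompkins style: band-pass 8–16 Hz (2nd-order Butterworth,
zero-phase), derivative, rectification, 80 ms moving-average integration.
Local maxima of the integrated signal (≥ 200 ms apart; the record
boundaries are eligible) are classified QRS/noise by an adaptive threshold
noise + 0.3125·(peak − noise), with both running estimates updated at
weight 0.125. A candidate within 360 ms of the previous QRS whose
integrated slope is under half the predecessor's is rejected as a T wave.
When the gap since the last QRS exceeds 1.5× the running average of the
last 8 RR intervals, the largest candidate in the gap is accepted at half
threshold (search-back). Each detection is finally relocated to the
absolute-maximum raw sample within ±40 ms, giving sample-resolution RR
intervals. The algorithm name fixes the structure but not the constants;
the values above are the published parameterization of this detector
family. All detected beats enter the RR series — no ectopic-beat
exclusion is applied.

## HRV features and segmentation

Windows are half-open [t₀, t₀ + 300 s), an interval belonging to the
window that contains its terminating beat time; a trailing partial window
is dropped, so 1800 s yields exactly six segments. The one exception is
the final window, which also keeps a beat landing exactly on the record
end — otherwise an interval terminating precisely at t = 1800 s would
vanish and interval count would not be conserved on exact grids.

The statistics follow the definitions in the README. Two conventions
deserve note, both kept deliberately and both configurable:

* **PNN50 divides by N** (the interval count), not by the N − 1
  successive differences, and compares strictly (> 50 ms);
* **NN50 compares with ≥ 50 ms**.

The asymmetry only matters for differences tied at exactly 50 ms and
changes PNN50 by a factor (N−1)/N; SDRR uses the population (1/N) form.
The ninth classifier input is the interval count N — the only remaining
per-segment quantity the pipeline computes. Feature columns may be
standardized per column; the scaler is fitted on training rows only and
reused verbatim for all evaluation rows.

## Classifier

The length-9 vector is treated as a one-channel sequence (an unusual but
faithful design: the "temporal" axis is the feature index). Architecture:
reshape to (9, 1) → per-timestep dense (64, ReLU) → for each block k with
dilation 2^k: two causal dilated convolutions (kernel 2, 64 filters) giving
the gated unit z = tanh(·) ⊙ σ(·), then a per-timestep dense (64, ReLU)
collected as a skip output; the skip sum passes ReLU → flatten (9 × 64 =
576) → dropout 0.5 → dense 512 ReLU → dropout 0.5 → dense 512 ReLU →
dense 5 softmax. Causal padding keeps the temporal length at 9 throughout,
so the flatten width is input_len × filters. Blocks feed forward
skip-sum-only by default; an opt-in `use_residual` flag adds the identity
path (the source description mentions residual connections in prose but
shows only skip summation in its layer walk-through, and its printed output
layer — 512 ReLU units yet a 5-wide output — is internally contradictory;
a 5-unit softmax is the only consistent reading). With 7 blocks the
receptive field (2⁷ = 128) covers the full input.

Everything is NumPy: explicit forward pass, hand-derived reverse-mode
gradients (validated against central finite differences to ~1e-6), Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), categorical cross-entropy, inverted
dropout. Loss and optimizer are the de-facto defaults for softmax
classifiers; the source does not state them. Weight initialization is
Glorot-uniform from a seeded generator; shuffling and dropout masks come
from the training seed; on a single thread two runs with equal seeds are
bit-identical. A non-finite loss aborts training with a diagnostic rather
than silently producing NaN weights — relevant at the largest grid
learning rate, where divergence is a legitimate outcome recorded as NaN in
the grid report.

## Experiment protocol

The split is at subject level (every segment of a subject on one side),
stratified by class via largest-remainder apportionment of the global
test count n − ⌊0.8·n⌋; 115 subjects split 92/23. Grid search trains one
seeded model per combination of hidden blocks {3, 5, 7, 9} × learning rate
{0.1, 0.01, 0.001, 0.0001} × batch size {32, 64, 128, 256} (64 models; a
restricted four-model list is available) on the first-segment rows of the
training subjects, and selects the highest first-segment test accuracy,
ties broken by lower test loss. The selected model is then evaluated
zero-shot — no retraining — on segments 1–6 of the held-out subjects. The
reference protocol trains for 140 epochs; the package's study-scale runs
use 20 epochs, which the separable synthetic cohort saturates, and the
epoch count is a parameter throughout.

Metrics derive from 5×5 confusion matrices (rows true, columns predicted,
class order CAD, CHF, NSR, SCD, VT). Per class c: TP = cm[c,c], FN = row −
TP, FP = column − TP, TN = total − TP − FN − FP; accuracy, sensitivity,
specificity, precision are the usual one-vs-rest ratios in percent. Macro
values are unweighted means over classes; a class with no positives has
undefined sensitivity, reported as NaN and excluded from the macro with a
warning. The pooled per-class report sums the six per-segment confusion
matrices before deriving metrics.

## Numerical choices and degenerate inputs

* Zero-variance RR profiles are exact (no random draws consumed for the
  deterministic components), so metronome fixtures are reproducible to the
  bit.
* A constant signal has no NADev/NADiff scale and raises a degenerate-input
  error; a flat record yields an empty annotation (not an error).
* Grid-search ties on accuracy resolve by lower loss; remaining ties keep
  the earlier combination in grid order.
* Detector relocation can merge two integrated-signal detections onto one
  raw extremum; a post-pass enforces the 200 ms refractory by keeping the
  larger-amplitude peak.
* CSV writers print floats with 17 significant digits and readers parse in
  round-trip mode, so record and feature tables round-trip bit-exactly.

## Problem sizes used by the test suite

Distributional checks use N ≈ 5·10³–10⁴ intervals; detector benchmarks use
50 noisy 60-second records at 250 Hz; the end-to-end study uses the full
115-subject, 30-minute cohort at 128 Hz with the complete 64-point grid at
20 epochs. These sizes were chosen so the whole suite exercises every
claim at study scale on a single CPU.

## Known limitations

* The synthetic cohort's separability is a design input, not a finding;
  held-out accuracy on it says nothing about discriminating real rhythm
  classes.
* The AR(1) process cannot express long-range correlation (detrended
  fluctuation structure) or respiratory sinus arrhythmia's oscillatory
  signature; frequency-domain and nonlinear HRV features are out of scope.
* The WFDB reader covers single-segment records in formats 212 and 16 with
  per-signal gain/baseline; annotation (.atr) files, EDF, and multi-segment
  records are unsupported.
* Treating the 9 heterogeneous features as a sequence axis is reproduced
  as designed; nothing here argues it is the right inductive bias.
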