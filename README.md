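# hrvnet

Heart-rate-variability analysis pipeline for sudden-cardiac-death (SCD) risk
stratification from single-channel ECG. The package implements, end to end
and fully testable offline:

1. **Synthetic ECG cohort generation** — five rhythm classes (normal sinus
   rhythm NSR, coronary artery disease CAD, congestive heart failure CHF,
   ventricular tachycardia VT, and pre-ventricular-fibrillation SCD), with
   RR intervals drawn from a truncated Gaussian AR(1) process and waveforms
   built from per-beat P-QRS-T Gaussian templates plus baseline wander,
   white noise and powerline interference. Every record carries ground-truth
   R-peak locations.
2. **Preprocessing** — discrete-wavelet-transform denoising (sym5): the
   sub-0.5 Hz approximation is zeroed to remove baseline wander and the
   finest detail levels are soft-thresholded; amplitude normalization by
   mean absolute deviation (NADev) or mean absolute successive difference
   (NADiff).
3. **R-peak detection** — a Hamilton–Tompkins detector (8–16 Hz band-pass,
   derivative, rectification, 80 ms moving-window integration, adaptive
   peak/noise thresholds with 200 ms refractory, T-wave rejection and
   search-back), with final relocation to the raw-signal extremum.
4. **HRV features** — each recording is segmented into 5-minute windows and
   eight time-domain statistics are computed per window:

   | symbol | definition |
   |---|---|
   | MRR    | (1/N) Σ RRᵢ |
   | SDRR   | √((1/N) Σ (RRᵢ − MRR)²) |
   | RMSSD  | √((1/(N−1)) Σ (RRᵢ₊₁ − RRᵢ)²) |
   | PNN50  | #{ \|ΔRR\| > 50 ms } / N |
   | CVRR   | SDRR / MRR |
   | NN50   | #{ \|ΔRR\| ≥ 50 ms } |
   | Min_RR, Max_RR | extrema of the RRᵢ |

   together with the interval count N, giving the length-9 classifier input.
5. **Classifier** — a 1-D gated dilated-convolution ("Wavenet"-style)
   network over the feature vector: per block k, z = tanh(W_f,k ∗ x) ⊙
   σ(W_g,k ∗ x) with causal dilated convolutions (kernel 2, dilations
   2⁰ … 2⁶), per-timestep dense maps collected as skip connections, and a
   flatten → dropout → dense(512) → dropout → dense(512) → softmax(5) head.
   Implemented in pure NumPy (explicit forward, reverse-mode gradients and
   Adam), so runs are bit-reproducible from their seeds.
6. **Experiment protocol** — stratified subject-level 80/20 split, an
   exhaustive hyperparameter grid search (hidden blocks {3,5,7,9} ×
   learning rate {0.1,0.01,0.001,0.0001} × batch size {32,64,128,256}) on
   the first 5-minute segment, then zero-shot evaluation of the selected
   model on all six segments of the held-out subjects, reported as 5×5
   confusion matrices with one-vs-rest accuracy/sensitivity/specificity/
   precision and unweighted macro averages.

The intended audience is researchers prototyping HRV-based risk models who
need a reference implementation whose every stage is verifiable against
known ground truth before touching clinical recordings (e.g. the PhysioNet
Holter databases; a WFDB reader for formats 212 and 16 is included).

## Worked example

```python
from hrvnet import (generate_rr, synthesize_ecg, preprocess, detect_rpeaks,
                    to_rr, compute_features)
from hrvnet.synthetic_ecg import DEFAULT_PROFILES, NoiseSpec

profile = DEFAULT_PROFILES["SCD"]                      # high-variability class
rr_true = generate_rr(profile, duration=300.0, seed=7)
record = synthesize_ecg(rr_true, fs=250.0,
                        noise=NoiseSpec(baseline_amp=0.2, white_sd=0.05),
                        seed=8, subject_id="scd-demo", label="SCD")
conditioned = preprocess(record)                       # DWT denoise + NADev
peaks = detect_rpeaks(conditioned)
features = compute_features(to_rr(peaks))

print(f"true beats: {record.ground_truth_peaks.size}, "
      f"detected: {peaks.peak_indices.size}")
print(f"MRR   = {features.MRR:.4f} s")
print(f"SDRR  = {features.SDRR:.4f} s")
print(f"RMSSD = {features.RMSSD:.4f} s")
print(f"PNN50 = {features.PNN50:.4f}, NN50 = {features.NN50}, N = {features.N}")
```

prints

```
true beats: 527, detected: 527
MRR   = 0.5699 s
SDRR  = 0.1020 s
RMSSD = 0.1300 s
PNN50 = 0.5380, NN50 = 283, N = 526
```

All 527 beats of the noisy 5-minute record are recovered; the mean RR
(0.57 s) and its dispersion (SDRR 0.10 s) sit near the generating process
(μ = 0.60 s, stationary SD 0.08 s) — the gap is the genuine contribution of
the shortened ectopic-like beats the SCD profile injects, which inflate
dispersion and depress the mean. The high PNN50/NN50 reflect the same
mechanism.

The full study protocol runs from the shell:

```
hrvnet pipeline --seed 1 --epochs 20 --out study.json
```

which generates the default 115-subject cohort (18 NSR / 51 CAD / 15 CHF /
11 VT / 20 SCD, 30 min each), extracts 690 per-segment feature rows, grid
searches the classifier on first segments of the 92 training subjects, and
evaluates on all six segments of the 23 held-out subjects. On the default
separable cohort the selected model reaches 100 % pooled held-out accuracy.

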