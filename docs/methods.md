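# Methods

This note documents the modelling choices behind `hrvprint`: what each
stage computes, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Data model

The unit of analysis is a beat-annotated RR-interval series: interval
durations in seconds, each labelled by the beat that ends it — `N` for a
sinus beat, `V` for a premature ventricular complex (PVC). A recording
carries a patient identifier and an outcome label, `pre_event` (capture
ending just before a VT/VF episode) or `control`. Intervals are kept in
seconds internally; reports print milliseconds.

## Standardisation

Recordings are truncated to their **last 1000 beats** so that short
pre-event captures and longer control exports cover comparable spans
(~15 min at typical rates). Recordings with a PVC among the final beats
are excluded: terminal ectopy may already be part of the arrhythmia onset
and would leak outcome information into the features. The tail window is
**10 beats** by default — the requirement is qualitative ("no PVCs at the
end") and 10 beats is a conservative, configurable reading.

The sinus-only (NN) series replaces each V-labelled interval *and* the
interval immediately after it (the one ending the compensatory pause;
neither is an NN interval) by linear interpolation between the nearest
unaffected N intervals. Linear interpolation was chosen over more
elaborate tachogram editing because it preserves series length and local
trend, is deterministic, and its behaviour is fully testable in closed
form. Edge PVCs (before the first or after the last clean N interval)
take the nearest clean value.

## HRV indices

Time domain: meanNN, SDNN, RMSSD, pNN50, with sample (n−1) denominators
for all SDs and a **strict** > 50 ms threshold for pNN50. "Last minute"
indices are the mean/SD over the maximal suffix of intervals whose
cumulative duration fits in 60 s (at least two intervals).

Frequency domain: the tachogram (NN duration vs beat time) is resampled
at **3 Hz by cubic spline** (no extrapolation beyond the last beat),
split into consecutive non-overlapping **300 s segments anchored at the
recording end** — the most recent physiology is always covered and any
partial segment at the start is dropped — and each segment is analysed
with Welch's method: linear detrending, Hanning window of **300 samples**
with **50 % overlap**, one-sided density normalisation so band integrals
approximate variance contributions in ms². LF is 0.04–0.15 Hz, HF
0.15–0.4 Hz; normalised units are defined as 100·band/(LF+HF), which
guarantees LFnu + HFnu = 100 and matches the usual convention when the
very-low-frequency band is excluded. Per-segment values are averaged
across segments. A segment with zero band power is excluded from the
ratio averages with a warning; if *every* segment is powerless (a
strictly constant tachogram) the ratios are reported as NaN rather than
failing the whole recording.

## Heartprint indices

The coupling interval (CI) of a PVC is read directly from its V-labelled
RR interval — the span from the preceding beat to the PVC — and only
PVCs preceded by a sinus beat contribute (a V→V interval is not a CI
against a sinus beat). NIB is the count of sinus beats strictly between
consecutive PVCs. Summaries: PVCs/hour, meanCI, SDCI, the modal NIB
value (exposed as `NIBmax`) and the number of NIB entries attaining the
mode (`sNIB`); both mode-as-value and mode-as-count are exposed because
both readings appear in the literature. Modal ties break toward the
smaller NIB value. With fewer than two PVCs the CI/NIB summaries are NaN
("undefined"), never a silent zero; before modelling these NaNs are
imputed with training-set medians (per cross-validation split, so no
leakage).

## Scaling and the classifier

Each index is mapped to (x − min)/(max − min) with the minimum and range
learned on training rows only; the same factors are applied to test data,
which may therefore fall outside [0, 1] — deliberately not clipped, as an
online detector would behave the same way.

The classifier is a soft-margin SVM with the RBF kernel
K(x_i, x_j) = exp(−γ‖x_i − x_j‖²) (libsvm backend via scikit-learn).
Hyperparameters come from a fixed grid — C ∈ {0.5, 1.0, …, 10.0} (20
values), γ ∈ {2^e : e = −15, −14.5, …, 3} (37 values) — and index
combinations from a greedy forward search: all C(16,2) = 120 pairs are
scored first, then one index is added per step, re-optimising (C, γ)
each time. Grid ties break toward smaller C, then smaller γ (simplest
model first).

Cross-validation is patient-paired: one pre-event/control pair per
eligible patient (chosen uniformly at random under the run seed when a
patient has several), whole patients dealt round-robin into 10 folds, so
each fold's prevalence is exactly 0.5 and the natural decision threshold
is the margin 0. The scaler and imputer are refit inside every split.
Held-out recordings are ranked by decision margin; fold AUC uses the
Mann–Whitney rank statistic with ties counted ½, and the reported values
are across-fold mean ± SD. The final model for a chosen combination size
is trained on *all* rows (not only the CV pairs), stored with its scaler,
imputation medians and support vectors as a JSON bundle, and evaluated on
held-out tables with a Hanley–McNeil 95 % CI for the AUC and a Wilson
95 % CI for accuracy.

## Synthetic cohorts

The generator exists to make every contract testable without clinical
data; it is deliberately minimal. The sinus stream is

NN(t) = meanNN + lf_amp·sin(2π·0.10·t + φ₁) + hf_amp·sin(2π·0.30·t + φ₂) + ε,

with ε white Gaussian noise, evaluated at running beat times — the
smallest model with independently controllable LF and HF content.
Autoregressive or integral-pulse-frequency-modulation models were
considered and rejected as unnecessary for testing extraction contracts.
PVCs are inserted at beat positions whose inter-PVC gaps are NIB draws
from a categorical distribution; the PVC count is fixed by
rate × expected duration, each PVC's interval is a coupling interval
drawn from a normal truncated to (0.2, 0.95)·meanNN, and the following
sinus interval is the fully compensatory pause 2·NN − CI. The final 10
beats are always PVC-free.

Cohorts pair a pre-event and a control parameter template per patient,
with one multiplicative log-normal jitter factor per parameter family
(mean NN, CI, PVC rate, oscillation amplitude) shared by both templates
of a patient, preserving within-patient effect directions. The default
templates centre on the reported group medians of the training
population: pre-event meanNN 676 ms, 159 PVCs/h, meanCI 520 ms, SDCI
63 ms and LF-dominant oscillation; control meanNN 787 ms, 71 PVCs/h,
meanCI 575 ms, SDCI 57 ms and balanced LF/HF. Interquartile ranges
loosely motivated the 5 % jitter SD.

What the generator does **not** emulate: circadian and respiratory
non-stationarity, autonomic drift in the minutes before an episode
(meanNN l.m. differs from meanNN only through the oscillations), complex
or multiform PVCs, and — at sparse PVC rates — the spread of PVCs across
the whole recording (the NIB-driven placement forms one contiguous block
with random PVC-free head and tail). Consequently a passing end-to-end
test shows the pipeline detects the planted effect structure under clean
conditions; it does not certify clinical performance.

## Problem sizes and numerical choices

Development and acceptance runs use 20-patient paired cohorts
(40 recordings of 1000 beats), a reduced 5-cost × 7-gamma grid for the
greedy search, and greedy chains capped at size 4; these sizes exercise
every code path while keeping a full run in the minutes range. The full
20 × 37 grid and 16-index chain are available through the same API.
Degenerate inputs are handled explicitly: constant scaled columns map to
0 with a warning; single-class folds or tables raise; all-tied scores
give AUC 0.5; γ → 0 drives the kernel toward all-ones and the margin
toward a constant (covered by a test).

## Known limitations

* Beat labels are taken as given; no beat classification from interval
  morphology is attempted, and label errors propagate into both index
  families.
* The linear-interpolation NN estimator is a simple surrogate for
  adaptive tachogram filtering; recordings dominated by long PVC runs
  leave little sinus signal to interpolate from.
* The Hanley–McNeil and Wilson intervals are large-sample
  approximations; at the 40-recording scale used here they are
  indicative, not exact.
* Cross-validation SDs are across folds of a single repetition;
  repeating the fold assignment under different seeds (supported via the
  fold-seed argument) gives a fuller picture of selection variability.
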