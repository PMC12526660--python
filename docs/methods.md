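# Methods

This note documents the models, numerical choices, and open design
decisions behind `hrvpipe`, stage by stage.

## Synthetic cohort generator (`hrvpipe.synthetic`)

The generator's defaults *are* the study conditions: they emulate the
population statistics of a large two-hospital single-lead ECG database —
age mean 58.0 / SD 13.98 years, mean heart rate 50.8 / SD 15.42 bpm,
balanced sex, 500 Hz sampling, two sites. Ages and heart rates are drawn
from truncated normals (age ∈ [20, 89] years, HR ∈ [30, 180] bpm; the
bounds are our choice — printed means/SDs alone admit impossible values).
Because truncation shifts and shrinks moments (naively ~+2.7 bpm on the
heart-rate mean), the parent parameters are solved by moment matching so
the *realized* mean/SD equal the configured ones; this is what makes the
calibration property (each moment within 3 standard errors at n ≥ 5000)
hold.

**RR series.** Intervals are mean RR plus i.i.d. Gaussian perturbations
with SD = target-RMSSD/√2, so the expected RMS of successive differences
equals the target. Intervals are floored at 250 ms (physiological
refractory); the floor only bites for extreme outlier targets.

**RMSSD mixture.** Each record's target RMSSD is band-typical with
probability `p_inlier` (default 0.8; drawn from its age band's fitted
normative normal, truncated at 0.1 ms) and otherwise from a heavy-tailed
log-normal (log-SD 1.0) matched to a 78.9 ms mean. The mixture is our
construction — the source population's typical/atypical composition is
not documented — chosen so both branches of the typicality scorer are
exercised. Record duration defaults to 60 s: RMSSD estimated from fewer
than ~10 intervals is extremely noisy, so shorter (e.g. 10 s) records are
available by config but not the default.

**Waveform.** One Gaussian QRS pulse (total width ≈ 80 ms) per R time on
a flat baseline, plus white noise with SD = `rmssd_noise_frac` ×
QRS amplitude (default 0.05). This is the minimal morphology the
R-peak-timing feature path consumes. It deliberately omits P/T waves,
arrhythmic morphologies, baseline wander and respiratory sinus
arrhythmia — so passing tests demonstrate the *pipeline's* correctness on
clean-ish signals, not detector robustness on pathological clinical ECG.

All randomness flows from one `SeedSequence`, so identical configs give
byte-identical cohorts across processes.

## R-peak detection (`hrvpipe.rpeak`)

Canonical Pan–Tompkins constants: 5–15 Hz 2nd-order Butterworth band-pass
(applied zero-phase), derivative, squaring, 150 ms moving-window
integration, signal/noise running estimates with threshold
N + 0.25(S − N), 200 ms refractory, search-back at half threshold when a
gap exceeds 1.66× the running mean RR. Fiducials are refined to the raw
signal's local maximum within ±50 ms, with a [1,2,1]-smoothed parabolic
vertex fit giving sub-sample timing. The sub-sample step matters: at
500 Hz the ±1 ms quantization alone would add ≈1.4 ms of spurious RMSSD,
which is material when band-typical values are only 2–16 ms. Detections
are invariant to amplitude scaling and baseline offset because every
threshold derives from the processed signal itself. A record with no
suprathreshold peak yields an *empty annotation plus a warning*, not an
exception, so batch runs skip and log bad records.

No ectopic/artifact rejection is applied before RMSSD — matching the
modeled workflow, which describes none.

## HRV features (`hrvpipe.hrv`)

RMSSD, mean HR, and R-peak count, computed in milliseconds internally.
The tabular surface stores `rmssd` in **seconds** to match the convention
of the emulated cohort's summary statistics; the labeler converts back to
ms. Records with fewer than 3 detections are flagged and excluded with a
log entry.

## Typicality labeling (`hrvpipe.labeling`)

The reference table ships two printed anchor decades — ages 20–29
(median 4.1–4.8 ms, total 1.3–16.1 ms) and 60–69 (median 2.04–2.07 ms,
total 0.5–10.4 ms) — and interpolates/extrapolates the other decades of
the 20–89 span linearly in (midpoint, width) space for both the median
and total ranges, with a small positive floor on extrapolated widths.
Interpolating the four endpoints independently would invert the medians
past age ~70, because the anchors' medians converge; the
(midpoint, width) parametrization keeps every band valid. The 60–69
median is printed in inverted order in the source material and is read
with the bounds corrected; a warning notes this when printed defaults are
used. The printed ranges sit an order of magnitude below common
physiological RMSSD norms — they are treated as data and preserved as
printed (a log message flags it), which is why most realistic RMSSD
values fall out-of-range and the generator's band-typical draws come from
the fitted normals rather than physiological norms.

**Fitted normal.** σ = 1000·(hi − lo)/(2·Φ⁻¹((1+c)/2)) with coverage
c = 0.96, so the total range spans the central 96% mass. The mean
defaults to the **range midpoint**, which is the only choice under which
(a) both boundaries sit at z = ±Φ⁻¹(0.98), (b) the boundary score equals
1 − c, and (c) draws from the fitted normal land in-range with
probability c. The alternative reading — mean at the midpoint of the
printed medians — is retained behind `center="median_midpoint"`; with the
shipped anchors that mean is far off-center and the coverage identity no
longer holds, so it is not the default.

**Score.** Two-sided mode (default): y = 2·min(Φ(z), 1−Φ(z)) inside the
total range — a typicality reading, maximal at the center, symmetric in
z. The literal one-sided CDF (y = Φ(z)) is available as `literal_cdf`;
it scores low RMSSD as maximally atypical and high RMSSD as maximally
typical, which contradicts "typical for the age group", hence the
default. Outside the range the score decays as
y(boundary)·exp(−λ·d/σ) with λ = 1 per σ (the decay rate is not
prescribed anywhere; one e-fold per σ is scale-free in the band's own
units). Anchoring the decay at the boundary score is our choice and
guarantees continuity (verified to <1e-6 jump at ε = 1e-6·σ). Scores are
clamped to [0, 1]. Sex plays no role in the label.

## Preprocessing (`hrvpipe.preprocess`)

Order: winsorize → collinearity merge → standardize. Capping is at the
5th/95th percentiles (linear-interpolation definition) as the operational
reading of an "IQR method capped at the 5th and 95th percentiles"; a
1.5×IQR fence mode exists for comparison. The Spearman screen flags
|ρ| > 0.85; each flagged pair is replaced by the mean of the two columns'
z-scores — symmetric and bell-shaped, unlike product or ratio
alternatives, matching the intended "normalized bell-shaped" synthetic
feature. The merged column is named with the later table column leading
(`r_peaks` + `mean_hr` → `r_peak_mean_hr`, the conventional name).
Standardization uses the population-SD convention (ddof = 0). Only the
features are winsorized, not the target.

The target is standardized alongside the features for regression — the
benchmark's headline R²/RMSE pair satisfies RMSE² = 1 − R² only on a
unit-variance target, which pins down that convention — while the raw
[0, 1] target is retained (`target_raw`) for thresholded classification.
All parameters are fit on the training split only and replayed on test
rows via the stored `PreprocessReport`, which reproduces the processed
table from raw input exactly.

## Models (`hrvpipe.models`)

Suite: linear regression, decision tree, random forest, XGBoost,
LightGBM (the two gradient-boosting implementations mirror the standard
lineup; the explainable boosting machine and deep sequence models are out
of scope). The tuned forest uses 111 trees with max depth 26. Splits are
80/20, stratified by target quintile; CV is 5-fold shuffled — community
defaults, fixed by seed. R² is computed as 1 − SSE/SST on the evaluation
set, and rmse = √mse to machine precision.

**Bayesian tuning.** `optimize_rf` minimizes k-fold CV MSE over an
integer box (trees ∈ [50, 300], depth ∈ [5, 40]) with a Matérn-5/2
Gaussian-process surrogate (normalized y, small white-noise term) and
expected-improvement acquisition over a random integer candidate pool of
256 points. The library-default anchor (100 trees, deepest allowed) is
always evaluated first, so the returned optimum is never worse than the
default. The trace records every (params, MSE) pair; `best_so_far` is
non-increasing by construction.

**Classification metrics.** The continuous target is binarized at a
threshold on the raw probability scale with Positive = atypical = score
< 0.5, applied identically to truth and prediction — the only symmetric,
parameter-free rule; the threshold used is recorded in every result.
Single-class truth yields precision/recall 0 with a warning.

**Federated variant.** One model per site, trained on local rows only;
aggregation is uniform averaging of per-site *predictions*, since tree
ensembles have no averageable parameters (FedAvg-style parameter
averaging is undefined for forests). A single partition degenerates to
centralized training exactly. `rounds` is accepted for interface
symmetry; prediction-level aggregation needs one round.

## Pipeline (`hrvpipe.pipeline`, CLI)

One top-level seed; per-stage seeds derive from it via `SeedSequence`.
The generator always draws from the shipped normative model (a study
condition), while the labeling stage uses the configurable reference
source — so a reference table that does not cover the cohort's ages
aborts with a labeling-stage error. Every stage logs row counts in/out;
reruns of the same config are byte-identical. Record signals stream
through feature extraction one at a time, so memory stays flat in cohort
size.

## Problem sizes

The shipped study scale is a 10,000-record cohort of 60 s records at
500 Hz for the regression benchmark, 5,000 records for the
rate/count-correlation check, and 100,000 Monte-Carlo draws for the
coverage construction; unit tests use smaller cohorts (40–600 records).

## Known limitations

- The label is a deterministic function of measured RMSSD and age, so the
  regression benchmark measures how well a forest fits a smooth
  two-variable function — strong performance here does not certify
  clinical predictive value on real cohorts.
- The waveform model is minimal; detector metrics on it do not transfer
  to noisy wearable ECG with arrhythmias or motion artifacts.
- Normative ranges outside the two anchor decades are interpolations, not
  published values, and are fully overridable by a CSV reference file.
- The WFDB support is a minimal single-channel format-16 reader/writer
  (header + int16 .dat with gain/offset and comment metadata), sufficient
  for interchange of this pipeline's records, not a general WFDB
  implementation; amplitudes are quantized at the header gain
  (4096 adu/mV by default).
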