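# Methods

## The estimator

The short-term scaling exponent α1 is computed per analysis window as:
mean-removal; cumulative summation; for each box size n = 4…16, partition into
⌊N/n⌋ non-overlapping boxes (trailing partial box discarded), least-squares
line fit per box, RMS residual pooled over all covered points into F(n); α1 is
the least-squares slope of log F(n) on log n. Windows with constant input or
fewer than two usable box sizes return NaN and are marked invalid.

**Small-scale calibration.** At boxes this small the fluctuation function of
even ideal white noise deviates from its asymptotic power law: with per-box
linear detrending the exact expectation is E[F²(n)] = σ²(n² − 4)/(15n), not
σ²n/15. Left uncorrected, the 4–16 beat slope of an uncorrelated series reads
≈ 0.58 rather than 0.5, and an H = 0.3 series ≈ 0.41. F(n) is therefore
divided by √(1 − 4/n²), the standard analytic white-noise deviation
correction. With it the estimator recovers generating exponents 0.3 / 0.5 /
0.75 / 1.0 with mean estimates 0.33 / 0.50 / 0.73 / 0.94 (n = 1000 beats, 200
replicates) — within the 0.1 closure budget everywhere. Maximal-overlap boxes
were evaluated and rejected: they reduce per-window scatter by only ~10% and
depart from the non-overlapping convention.

**Windowing.** Time-varying mode evaluates a fixed-width window (default
120 s) on a fixed grid (default 5 s); a window ending at t takes the beats in
(t − 120, t], so a T-second recording yields ⌊(T − 120)/5⌋ + 1 windows.
Windows are right-aligned (result stamped at the window end) for causal /
real-time consistency; center-assignment would shift threshold *times* but
barely threshold *heart rates*, because window-mean α1 and window-mean HR lag
equally. Beat-count (real-time) mode evaluates the prior 200 beats at every
beat. Both modes share one evaluation chain: smoothness-priors detrending of
the window, then α1. Windows need ≥ 100 beats (the sufficiency floor for
2-min windows) and, by default, ≤ 5% corrected beats; the artifact gate is a
config field (`DFAConfig.max_artifact_pct`) because the bias experiments must
evaluate windows above it.

**Detrending.** Smoothness priors: trend = (I + λ²D₂ᵀD₂)⁻¹z with the
second-difference operator D₂ and λ = 500 (dimensionless, the convention for
RR work); the window mean is removed first and not restored, and z − trend is
passed to the estimator. λ = 0 degenerates to "trend = signal" (output zero).
For a ~200-beat window, λ = 500 passes fluctuations up to periods of roughly
140 beats, far above the 4–16-beat boxes, so its effect on α1 is
second-order. The solve uses a symmetric pentadiagonal banded factorization.
Order of operations in the pipeline is fixed as: artifact correction →
windowing → detrending → DFA.

## Artifact handling

Missed beats (dropped QRS detections) merge two true intervals into one
roughly doubled interval. Two detectors are provided:

* **Threshold family** — flag interval i iff |rr[i] − local median| exceeds a
  named absolute level (very_low 0.45 s … very_strong 0.05 s; *medium*
  0.25 s is the default). The local median uses the 11 nearest non-flagged
  intervals (self excluded, edges truncated); flags grow to a fixpoint so
  clustered artifacts cannot hide inside their own reference median.
* **Automatic** — a robust successive-difference classifier: each beat's
  difference is standardized by a quartile-based z over a 91-beat sliding
  context and flagged above 5.2, *conjoined* with a value-deviation criterion
  (robust z of |rr − local median| above half the cutoff). The conjunction
  matters: a large successive difference implicates two beats, and without it
  the normal successor of every merged beat is also flagged, doubling the
  correction footprint. A merged-beat pattern rule (interval > 1.6× local
  median) catches doubled intervals whose difference score alone is
  borderline.

**Correction.** A flagged interval above 1.75× its local median is split into
round(rr/median) equal sub-intervals, restoring the lost beat count. All
flagged positions are then imputed by a cubic spline through the non-flagged
intervals **plus a stochastic residual**: Gaussian noise with sd equal to
0.85 × the robust local beat-to-beat deviation (MAD over a 41-beat
neighborhood). The residual is essential, not cosmetic: a bare interpolant is
a conditional mean and therefore under-dispersed, which measurably inflates
α1 in every regime and drags the HRVT by ~2 bpm at 6% artifact. With
variance-matched imputation the α1 bias pattern becomes proportional —
positive where the true dynamics are anticorrelated (white residuals cannot
reproduce anticorrelation), near zero mid-range, slightly negative in very
smooth high-α1 segments — and the HRVT moves by well under 1 bpm. The 0.85
factor discounts the share of local deviation the spline itself predicts; 1.0
over-roughens correlated segments. Imputation is seeded (default 0), so
correction is deterministic unless a generator is passed. Each contiguous
corrected run is rescaled so its duration matches the original exactly.

**Injection.** For experiments, `inject_missed_beats` deletes
round(pct/100 · n) interior beats chosen uniformly without replacement, no
two adjacent, merging each deleted beat's two intervals; total duration is
conserved exactly and the log records deleted positions in both coordinate
systems. The 20% cap keeps the non-adjacency constraint trivially satisfiable.

## Threshold estimation

Default: OLS of α1 on the predictor (HR by default; time and power
available) over valid windows with α1 ∈ [0.4, 1.0] — the descent band,
excluding the correlated pre-ramp plateau and the anticorrelated floor — then
solve for the target (0.75 or 0.5). If the fit is non-descending or r² < 0.5,
fall back to first-crossing linear interpolation on the 4-point-smoothed
series, with a QC flag; if α1 never reaches the target, return no value and a
`no_crossing` flag. The pair estimator enforces HRVT2 at or above HRVT and
flags both otherwise. On an exactly affine α1–predictor profile the estimate
is exact to numerical precision, and adding c bpm to every window shifts the
HR estimate by exactly c.

**Known behavior at the 0.5 target.** Under realistic conditions RR
variability shrinks roughly tenfold from rest to peak (vagal withdrawal, see
below). The early, higher-variance part of each 2-min window then dominates
the pooled fluctuation function, so the rolling series reads the 0.5 crossing
systematically late — ~+0.03 α1 at the descent tail, i.e. 5–15 bpm high
depending on noise, across every estimation route tried (global band
regression, local-in-time and local-in-alpha regression, first crossing,
quadratic descent fit). HRVT (0.75) sits mid-ramp where the variance gradient
is milder and recovers with a ~3 bpm median error. This mirrors the wide
limits of agreement reported for second-threshold estimates in practice and
is documented rather than hidden: the recovery tests assert 3 bpm for HRVT
and a 20 bpm budget for HRVT2 with ordering preserved.

## Synthetic data

Fractional Gaussian noise with Hurst exponent H is the ground-truth process:
its DFA exponent equals H. H < 1 uses exact circulant embedding
(Davies–Harte); the output is returned without per-sample restandardization,
because re-centering by the sample mean biases the autocovariance that tests
check against the closed form ρ(1) = 2^(2H−1) − 1. Resting HRV shows α1 up
to ~1.2, beyond fGn's range, so 1 ≤ H < 1.5 is synthesized spectrally with
power spectrum ∝ f^−(2H−1) (exactly 1/f at H = 1), which has the same DFA
exponent.

Exercise ramps are piecewise-stationary segments — each with target exponent,
mean RR and RR deviation — joined by 30-s linear cross-fades; inside a fade
the two adjacent fGn streams are mixed with variance-normalized weights.
Piecewise stationarity keeps the per-window "true" exponent well defined.
The default incremental ramp (clean_ramp) runs 20 min over ten 120-s
segments: exponent 1.1 → 0.3, mean RR 850 → 330 ms (HR 71 → 182 bpm), and RR
deviation 40 → 3 ms, a geometric decline emulating vagal withdrawal — this
amplitude profile is a plausibility device, not a validated autonomic model,
but it is required for artifact thresholds to behave realistically across the
ramp. Optional iid Gaussian jitter models device timing error; the catalog's
noisy variant uses 4 ms, and recovery studies span 0/2/4 ms, bracketing
consumer chest-belt R-peak precision (~1–4 ms). The truth log stores the
faded exponent and mean-RR trajectories at 1 Hz and the interpolated heart
rate at the 0.75 and 0.5 crossings.

What the generator does **not** emulate: respiratory sinus arrhythmia and
cardiolocomotor coupling, ectopy and morphology-dependent artifacts,
breathing-rate changes, and the occasional large genuine RR excursions of
high-HRV individuals at rest. The last omission matters for one result: with
real ECG data, fixed-threshold correction also clips genuine resting
excursions, which is a plausible contributor to negative high-α1 bias there;
in this synthetic bed the (smaller) negative high-α1 bias arises only from
the imputation residual. Passing tests therefore demonstrate internal
consistency and robustness of the chain, not field agreement with
gas-exchange thresholds.

## Experiments

The bias experiment clones a clean synthetic recording (control arm),
injects missed beats at 1/3/6%, corrects with either detector, re-runs the
rolling analysis, and matches windows across arms by end time (windows
invalid in either arm are dropped pairwise; the artifact QC gate is disabled
in both arms — the experiment's purpose is to measure what happens above
it). Level 0 short-circuits to an exact self-comparison. Reported per
(level, method): mean α1 bias, maximum |proportional bias|, and the HRVT
shift. Because the clean arm is synthetic, only the bounded qualitative
claims are expected to transfer (negligible bias at 1–3%, dual-sign
proportional pattern at 6%, sub-bpm central HRVT shift) — not any exact
bias percentage. The HRVT shift carries ~1.4 bpm of irreducible paired
re-estimation noise per replicate (the spline's deviation from the true
deleted beats is fixed given an injection; averaging over multiple
imputations was tried and does not remove it), so the central (median
signed) shift is the systematic quantity; per-replicate absolute shifts are
bounded more loosely.

## Problem sizes and defaults

| Quantity | Default | Why |
| --- | --- | --- |
| Box sizes | 4–16 beats | short-term convention |
| Window / grid | 120 s / 5 s | time-varying analysis convention |
| Real-time window | 200 beats | beat-count display convention |
| min beats per window | 100 | validity floor for 2-min windows |
| Artifact QC limit | 5% corrected beats | reporting convention for usable windows |
| Detrending λ | 500 | RR-series convention |
| Threshold band | α1 ∈ [0.4, 1.0] | the near-linear descent segment |
| Regime anchors | 100 replicates × 1000 beats | sub-minute runtime, ±0.004 SE |
| Closure | 200 replicates per H | ±0.003 SE at 0.1 tolerance |
| Robustness | 20 replicates × 20-min ramps | minutes-scale runtime, stable medians |

Runtime of the full test suite is ~2 minutes on one CPU; the acceptance
script runs in well under one.

## Limitations

* HRVT2 is read late under realistic variance decline (see above); treat the
  0.5 crossing as indicative, and prefer HRVT for zone anchoring.
* Recording-device bias (reduced R-peak timing precision whitening the
  series and lowering α1) is modeled only as iid jitter.
* The automatic detector is a behavior-class reconstruction of published
  robust successive-difference classifiers, not a clone of any proprietary
  implementation; constants (context 91 beats, z cutoff 5.2) are exposed.
* Results from other DFA implementations may differ in the second decimal
  from box-range, overlap and calibration conventions.
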