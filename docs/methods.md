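# Methods

This note documents the processing model, the defaults and why they were
chosen, the synthetic-data assumptions, and the numerical corner cases. It
states nothing that the test suite or `scripts/acceptance.py` does not
itself compute.

## Acquisition model

The target device samples each LED channel at 200 Hz and averages every 4
samples on-chip, yielding an effective 50 Hz stream; a 30 s buffer therefore
holds exactly 1500 samples. `AcquisitionConfig` carries these three numbers
and derives the rest; any consistent combination is accepted (e.g. 400 Hz /
factor 4 → 100 Hz, 3000-sample buffer).

## Preprocessing

**DC removal.** The raw PPG rides on a large, slowly varying DC level. A
trailing (causal) moving average over `W` samples estimates the trend, where
`W` is the smallest power of two ≥ `fs × max_ibi` (64 at 50 Hz with a 1 s
maximal interbeat interval) — a power of two so a microcontroller can divide
by bit shift, and between one and two maximal heartbeats long so it smooths
beats without tracking them. The input is delayed by `⌊W/2⌋` samples before
subtraction so the trailing window is effectively centred on the sample it
corrects, which minimises phase distortion of the trend estimate. The first
`W − 1` output samples are warm-up, flagged via `PPGSignal.valid_from` and
excluded from downstream statistics; output length always equals input
length.

**Band-pass FIR.** Resting pulse rates reach down to ~40 bpm and exercise/
tachycardia up to ~210 bpm, i.e. fundamentals of 0.7–3.5 Hz; everything
outside that band is noise for pulse detection. The filter is an equiripple
linear-phase band-pass from the Parks–McClellan (Remez exchange) algorithm
with transition half-width 0.3 Hz on each edge. Default length is **111
taps** at 50 Hz: on a 0.01 Hz frequency sweep this achieves pass- and
stop-band ripples of ≈ 0.045, meeting the 0.05 targets, whereas 101 taps
measures 0.051 and just misses them. Tap count, edges, transition and the
achieved ripples are all exposed on the `FIRFilter` object. Filtering is a
causal convolution; the group delay `(n_taps − 1)/2` is reported so peak
indices can be re-aligned to raw-signal coordinates exactly (the filter is
linear-phase, so the delay is frequency-independent).

**Standalone windows and padding.** On the device the filters run
continuously, so a 30 s buffer is just a slice of an already-warmed stream.
An offline 30 s file has no such history: the causal warm-up
(`W − 1 + n_taps − 1` ≈ 3.4 s at 50 Hz) would swallow the first beats, and
the group delay would hide the last ~1.1 s of beats beyond the buffer end.
The window orchestrator (`process_window`) therefore pads both ends with
**anti-symmetric (odd) reflections** of the signal before filtering and
discards them afterwards. Odd reflection continues the slope through the
boundary, so the joint itself can never become a local maximum; plain
mirror reflection was observed to create spurious boundary peaks whenever
the signal ended on a rising edge. The library-level stages stay strictly
causal and flag warm-up; padding is purely a window-level concern.

## Peak detection

Detection mimics a streaming implementation. A candidate is emitted at the
apex of a rising-to-falling monotony change when the apex strictly exceeds
its `k` preceding samples, with `k = ⌈(fs × 60/hr_max)/2⌉` — the rising-edge
span at the maximal supported heart rate (7 samples at 50 Hz, 220 bpm). The
decision is confirmed one sample after the apex, as a real-time device
would.

Candidates then pass two selection rules with interpretable knobs:

* **spacing** — no two peaks closer than `⌊fs × 60/220⌋` samples (13 at
  50 Hz); within a violating cluster the largest amplitude survives, ties
  keep the earlier index;
* **amplitude gate** — a candidate below `θ = 0.5` times the running median
  of the last `m = 5` accepted amplitudes is rejected. This removes
  diastolic bumps (typically ≤ ~0.5 of systolic amplitude after
  band-passing) and noise blips while adapting to slow amplitude drift.

Identical input always yields an identical peak list, and no reported index
lies in the warm-up region.

## Pulse rate and SpO2

Pulse rate is beat count scaled to a minute — exactly `count × 2` for the
30 s buffer. Zero detected beats returns 0 bpm with a quality flag rather
than an error.

For SpO2, each channel's DC is the mean of the (kept, not subtracted)
moving-average trend over the post-warm-up span; AC is the mean per-beat
peak-to-trough excursion of the band-passed signal, the trough being the
minimum between consecutive systolic peaks — a beat-aligned, outlier-robust
definition consistent with pulse-oximetry practice. The ratio of ratios
`R = (AC_red/DC_red)/(AC_ir/DC_ir)` feeds the quadratic calibration
`SpO2 = aR² + bR + c`, clamped to [0, 100] and reported to one decimal. The
default coefficients (−45.060, 30.354, 94.845) are the sensor family's
published reference curve; real deployments re-calibrate clinically, so the
triple is a config value, not a constant. With the defaults the curve is
monotonically non-increasing over R ∈ [0.4, 3.0] and the clamp engages
near R ≈ 2.5. A truly pulseless channel (constant offset) reports AC = 0
rather than erroring; any other channel with fewer than two detected beats
raises.

## PRV features

Interbeat intervals are successive peak-index differences divided by the
sampling rate, in milliseconds. Ectopic beats are corrected in **one pass**:
mean and standard deviation (population convention) are computed once over
the window, and any interval with |z| > 3 is replaced by the window median.
The z cut-off is configurable; 3.0 is the conventional default. One pass,
no re-estimation — so the operation is idempotent, which the suite checks
property-style.

The six features are frozen in order: mean IBI, IBI standard deviation
(population, n-denominator), peak count, RMSSD = √(mean(diff(IBI)²)),
excess kurtosis (normal → 0) and Fisher–Pearson skewness, both biased
estimators — the defaults of the usual scientific-Python stack. A
zero-variance window returns kurtosis = skewness = 0 with a quality flag so
the classifier input stays total and finite. All six match an independent
direct-moment implementation to 1e-9 (acceptance measures ~1e-14).

## Stress classifier

Stress detection is binary (0 = no stress, 1 = stress) on the 6-feature
vector. Training follows the standard imbalanced-classification recipe:

* **SMOTE** balancing, implemented in-package (minority-neighbor convex
  interpolation, k = 5, full balancing, explicit seed). Applied strictly
  inside training folds; leakage is guarded by construction and by test.
* One of three **pipeline shapes** — classifier; scaler + classifier;
  scaler + PCA + classifier — with scalers {standard, minmax, robust} and a
  registry of classifier families (LDA, k-NN, SVM, decision tree, naive
  Bayes, bagging, random forest, extra trees, gradient boosting).
* **Stratified shuffle-split** cross-validation with accuracy and F1; a
  most-frequent-label dummy baseline as the floor; exhaustive grid search
  with deterministic tie-breaking (accuracy, then F1, then lexicographic
  spec order).
* **Subject-level holdout** for the final report: `evaluate` refuses any
  overlap between training and held-out subject ids.

The shipped default is **standard scaler + linear-kernel SVM**, chosen
because its inference flattens to four arrays: `w` (hyperplane), `c`
(negative intercept), `u` (feature means), `p` (inverse standard
deviations); a label is `1` iff `wᵀ(p ⊙ (x − u)) > c`, costing 2d
multiplications, 2d−1 additions and one comparison for d = 6. Exact
equality scores label 0 (deterministic strict inequality). The default
hyperparameter grid (SVM C ∈ {0.1, 1, 10, 100}; PCA components 2–6; tree
depths {3, 5, 10, none}; ensemble sizes {100, 300}) is a documented
starting point, not a claim about any particular dataset; users supply
their own grids.

`embedded_infer` reproduces the flat-array arithmetic, optionally entirely
in 32-bit floats (the constrained-target path). The suite and acceptance
script verify 100% label agreement with the full scikit-learn pipeline on
1000 random vectors away from the decision margin (|score − c| > 1e-6; the
single-vs-double comparison uses 1e-4), and that a JSON round trip of the
model changes no inference.

## Synthetic data: what it emulates, what it does not

The generator produces the features the pipeline keys on, with exact ground
truth:

* **Beat trains** — IBIs from a truncated normal on [273, 2000] ms
  (220–30 bpm). `typical_ibi_sd` maps mean heart rate to a realistic IBI
  spread (45 ms at 40 bpm shrinking to 8 ms at 180 bpm), encoding vagal
  withdrawal at high rates; a flat large spread at 180 bpm would be
  physiologically wrong and over-modulates beat amplitudes through the
  band-pass edge.
* **Waveforms** — per beat, a dominant systolic Gaussian (amplitude 1 a.u.,
  σ = 45 ms) plus a delayed smaller diastolic Gaussian (ratio 0.35, delay
  250 ms, σ = 80 ms), on a DC offset of 100 a.u. with sinusoidal baseline
  wander (0.5 a.u. at 0.25 Hz), white noise (σ = 0.02 a.u.) and optional
  Gaussian motion-artifact bursts. The exact systolic apex sample of every
  beat is returned as ground truth.
* **Dual channels** — red and IR share one beat train and pulse shape; the
  red amplitude is rescaled so the prescribed ratio-of-ratios is exact, and
  because the shapes match, shape-dependent attenuation cancels in the
  measured ratio (acceptance measures round-trip error ≈ 0.003 against a
  0.05 tolerance).
* **Labeled PRV regimes** — baseline: mean IBI 850 ms, sd 50 ms, RMSSD
  45 ms; stress: 700 ms, 30 ms, 22 ms — the direction of sympathetic
  activation. Per-window IBI series are AR(1) processes matched to the
  regime's spread and RMSSD (ρ = 1 − RMSSD²/(2σ²)), with per-subject
  offsets (mean shift σ = 30 ms, RMSSD scale jitter); the *real* ectopic
  correction and feature extractor produce each row. Optional imbalance
  generates fewer stress windows (0.64 reproduces a 64/36 split whose
  majority baseline scores ~64%).

Not modeled: optical transmittance physics, realistic motion artifacts
beyond additive bursts, respiratory sinus arrhythmia structure, sensor
quantisation, or inter-subject morphology differences. Consequently, the
passing recovery experiments demonstrate that the pipeline is *correctly
implemented and internally consistent* — that peaks, intervals, features
and the classifier chain recover what was prescribed — not that any given
accuracy will transfer to real wrist recordings, where class overlap is far
larger than these well-separated regimes.

## Problem sizes and determinism

The suite and acceptance script run at desk scale: 25 thirty-second windows
(5 heart rates × 5 seeds) for detection metrics, 1000 vectors for inference
equivalence, three ratio targets for SpO2, and 5 seeds × 15 subjects ×
40 windows for classifier recovery with a 12/3 subject split — sizes at
which every check completes in seconds while the law-of-large-numbers
margins stay comfortable. Every stochastic operation takes an explicit
seed, and identical seeds produce byte-identical outputs (CSV included).

## Known limitations

* The amplitude gate assumes roughly stationary per-window amplitude; severe
  amplitude steps (e.g. cuff-like occlusion) could drop valid beats for up
  to `m` accepted peaks.
* The SpO2 AC estimate needs at least two detected beats in the analysis
  span; very low heart rates with short spans degrade it (use a longer
  window in config).
* The one-pass ectopic correction can leave a second, smaller outlier
  uncorrected if a larger one inflates the window standard deviation.
* Pulse rate is quantised to 2 bpm by the 30 s count rule — an inherent
  property of the counting method, not of this implementation.
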