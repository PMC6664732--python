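# Methods

This note documents the models, conventions and numerical choices
behind `fatiguenet`, and what the synthetic-data experiments do and do
not demonstrate.

## Synthetic EEG generator

`simulate.generate_recording` builds each channel as

```
x(t) = noise_sd * b(t) + A_alpha * g_alpha * o_alpha(t) + A_beta * g_beta * o_beta(t)
```

* `b(t)` — Gaussian `1/f^beta` background (beta = 1.0 by default),
  synthesized in the frequency domain and normalized to unit RMS. 1/f
  is the standard first-order approximation of resting EEG; the
  generator has no artifact model (no blinks, EMG, electrode drift) and
  no within-recording state transitions.
* `o_band(t)` — a unit-RMS rhythm per band: a sinusoid at a random
  in-band frequency with random phase, plus frequency-masked narrowband
  noise. Alpha is 8–13 Hz, beta 13–20 Hz.
* Gains: a *topographic* gain (`band_gains`) gives posterior channels
  (P3, Pz, P4, O1, Oz, O2 by default) 1.5× alpha and 1.2× beta in both
  states — alpha is physiologically posterior-dominant — and the
  *state* gains `fatigue_alpha_gain` / `fatigue_beta_gain` (default 2.0
  each) multiply the affected channels' oscillation amplitudes in the
  fatigue state only.

Default amplitudes are RMS microvolts: background 10, alpha 5
(posterior-weighted), beta 2.5. They were fixed once, at design time,
to give a clearly detectable but not saturating spectral contrast —
the generator exists to exercise the pipeline with a controllable
effect size, not to be a biophysical forward model. All random draws
happen in a state-independent order, so an awake and a fatigue
recording with the same seed differ only by the deterministic gain
pattern; `generate_dataset` derives per-(subject, state) seeds from the
master seed and jitters per-subject amplitudes by ±10 % so subjects are
not statistical clones.

**What passing tests show:** the pipeline recovers a band-power
contrast of the documented spatial/spectral shape from realistic
backgrounds at realistic SNR. They do not show robustness to
artifacts, non-stationarity, inter-session variability or electrode
noise — properties real driving EEG has and this generator deliberately
omits.

## Preprocessing

Order of operations: crop to the analysis span (default first 20
minutes) → polyphase anti-aliased resampling 500 → 200 Hz
(`scipy.signal.resample_poly`) → Butterworth bandpass 0.1–45 Hz of
prototype order 3 → non-overlapping 10-s windows, trailing remainder
dropped. The bandpass is causal single-pass by default; nothing in the
stated design implies zero-phase filtering, but a forward–backward
option (`zero_phase=True`, effective order 6) exists because it is
common practice in offline EEG work.

## Per-epoch PCA

Each epoch is reduced independently: rows (channels) are the
observations, time-points the variables, so at most m − 1 = 31
components are non-trivial and everything is computed from the economy
SVD of the centered 32 × 2000 matrix — no 2000 × 2000 covariance is
ever formed. Component signs follow a deterministic rule (largest-
magnitude loading positive) so results are reproducible across BLAS
builds.

Retention is `fixed_r` (default r = 20) or `variance_threshold`
(smallest r with cumulative explained variance ≥ 0.99). On broadband
synthetic data the 99 % rule selects nearly all 31 components — a
noise-dominated spectrum is almost flat — so the 20-component default
is the meaningful operating point here, and threshold mode harmonizes
differing per-epoch r to the dataset maximum so PCANet sees one
geometry. Because the basis is per-epoch, score column j of one epoch
is not comparable with column j of another; PCANet only consumes local
structure of the score matrix, so this does not matter downstream, but
a `basis="pooled"` mode (one basis for all epochs) is available for
anything that needs cross-epoch comparability.

## PCANet

* Patches: dense stride-1 k1 × k2 windows, per-patch mean removed,
  column-major vectorized (MATLAB convention). Patch size is a free
  parameter; the default 5 × 5 is odd (for centered same-size
  convolution) and small relative to the 32 × 20 reduced epochs.
* Filters: top eigenvectors (by eigenvalue, `numpy.linalg.eigh`) of the
  pooled patch covariance Σ X Xᵀ / (total columns), same sign rule as
  the PCA step. Layer-2 filters are learned from the pooled patches of
  all L1 layer-1 output maps; a `per_map` mode (one bank per layer-1
  filter) exists but pooled is the default, matching the original
  PCANet construction.
* Convolution is sliding cross-correlation without kernel flip,
  zero-padded to the input size. The choice of correlation vs true
  convolution is a sign convention on the learned (sign-fixed) kernels;
  it is fixed and used identically in learning and inference.
* Hashing: bit p of the hash is set iff the p-th layer-2 response is
  strictly positive (an exact zero counts as 0), so hash values lie in
  [0, 2^L2 − 1] and features are invariant to positive rescaling of the
  input epoch.
* Histograms: default 8 × 5 non-overlapping blocks on the 32 × 20
  geometry (B = 16), giving the 2^8 · 8 · 16 = 32 768-dimensional
  default feature. Blocks advance by `block × (1 − overlap)`; trailing
  partial blocks are dropped. For raw 32 × 2000 epochs the traditional
  variant defaults to m/4 × n/4 blocks (again B = 16) so both variants
  produce equally sized features at equal filter counts.
* Default L1 = L2 = 8; per-subject accuracy typically peaks around
  8–12 filters, and `evaluate.filter_sweep` covers the 2–14 range.

## Baseline features

* **Band power:** `scipy.signal.spectrogram` (Hann 128, 50 % overlap,
  PSD scaling), squared magnitudes averaged over frames, then over the
  FFT bins with low ≤ f < high per band (the last band closed at
  45 Hz); band edges delta 0.1–4, theta 4–8, alpha 8–13, beta 13–20,
  gamma 20–45 Hz. Frames are averaged before band averaging; with a
  mean this is associative, so the order is a documentation detail.
* **Wavelet packets:** full tree to level 3, `db4`, half-sample
  symmetric extension, terminal nodes in natural order. Daubechies-4
  (filter length 8) is the order for which a 2000-point signal gives
  exactly 256 coefficients per leaf under the `floor((len+7)/2)`
  recursion; lower/higher orders would not reproduce the 8 × 256
  structure. The wavelet-packet (equal-bandwidth, 8-leaf) reading is
  used rather than a plain DWT ladder, since only it yields eight
  equally sized coefficient groups.

## Evaluation

Stratified 10-fold CV by default (a non-stratified mode exists);
splits are deterministic given `shuffle_seed`. Any fitted feature
model — the PCANet banks — is learned inside each fold on the training
split only; the per-epoch PCA step is per-sample and therefore
fold-safe to precompute. Classifiers: `sklearn` SVC (linear, C = 1)
and KNN (k = 5); kernel, C and k are conventional defaults for
high-dimensional histogram features, all configurable. AUC is the
rank/Mann–Whitney statistic with ties at ½, computed per fold on
decision-function scores (SVM) or positive-class vote fractions (KNN)
and averaged over folds (pooling decision scores across folds would mix
incomparable scales). Method comparisons are two-sided paired t-tests
on per-subject means, reported uncorrected (a Holm adjustment can be
applied by the caller); degenerate zero-variance differences are
reported as t = 0, p = 1 (all-zero) or t = ±∞, p = 0 (constant
non-zero). Feature-extraction wall times are recorded for the
modified-vs-traditional efficiency comparison but only their *ordering*
is ever asserted; absolute seconds are machine-dependent.

Problem sizes in the shipped experiments — e.g. 2 subjects × 100 epochs
per state for the classification study, 6 epochs for the timing
contrast, 20 label permutations for the chance-level check — were
chosen as the smallest sizes at which the corresponding statistics are
stable.

## I/O and orchestration

Recordings travel as a compressed `.npz` (array + JSON metadata
sidecar), chosen over a bespoke binary for inspectability. EDF is
read through MNE (16-bit, converted to µV); EDF export is not
implemented. `pipeline.run_pipeline` validates every config section
before any computation, runs simulate → preprocess → evaluate, and
writes a manifest (config snapshot, per-stage timings, output
checksums) so a run is reproducible from its manifest plus seed.

## Known limitations

* The synthetic generator omits artifacts, drift and state dynamics
  (see above); accuracies on it say nothing quantitative about human
  recordings.
* Per-epoch PCA discards the cross-epoch meaning of component indices;
  interpretability of individual PCANet features is limited by design.
* The histogram block geometry and patch size are heuristics; no
  automatic selection is provided beyond the filter-count sweep.
* Timing comparisons are environment-dependent and reported, never
  asserted as magnitudes.
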