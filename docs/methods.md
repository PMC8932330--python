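# Methods

`fatiguefuse` estimates the exercise-fatigue state of a person in
rehabilitation training from one ECG channel and two surface-EMG (sEMG)
channels recorded synchronously at 2 kHz. The state is a three-level label
reported by the subject on the Borg perceived-exertion scale every 30 s:
relaxed (−1), transition (0), tired (+1). This note documents the model,
the synthetic data it is validated on, the numerical choices, and what the
validation does and does not show.

## Signal model and preprocessing

Raw windows pass through a fixed chain:

1. **Zero-phase low-pass** (Butterworth order 4, forward–backward): 100 Hz
   for ECG, 500 Hz for sEMG. Zero-phase filtering is used throughout so
   R-peak timing — the basis of all heart-rate-variability features — is
   not shifted.
2. **Adaptive powerline notch** at 50 Hz and its harmonics inside the
   channel passband (100, 150 Hz for sEMG; up to 100 Hz for ECG). The
   canceler generates an internal sin/cos reference per target frequency
   and adapts two LMS weights (step size µ = 5·10⁻⁴), which tracks slow
   amplitude/phase drift of the interference in a 49.5–50 Hz band while
   leaving neighbouring physiological content (e.g. 40 Hz) within 2%. A
   warm-start pass converges the weights before the output pass so the
   adaptation transient does not leak interference. A fixed zero-phase IIR
   notch is available as `method="iir"`. The LMS inner loop is compiled
   with numba when available, with an equivalent pure-Python fallback.
3. **EMD + wavelet denoising.** The signal is decomposed into intrinsic
   mode functions by classical sifting (cubic-spline envelopes, mirrored
   boundary extrema, Cauchy stop criterion 0.2, ≤ 50 sifts per mode). The
   first `n_initial_imfs` (default 3) IMFs — the scales where wideband
   noise concentrates at 2 kHz — are wavelet-thresholded rather than
   discarded: db4, 4 levels, soft universal threshold with the noise scale
   from the MAD of the finest detail coefficients. The signal is rebuilt
   as thresholded initial IMFs + remaining IMFs + residue. With
   thresholding disabled the reconstruction is exact to machine precision
   (IMFs are successively subtracted, so completeness holds by
   construction). All stages preserve length and sampling rate.

The EMD implementation is authored in this package (no EMD library is part
of the dependency set); its completeness property and denoising gain are
tested directly.

## The 11 fatigue features

ECG block (a = 3), computed from R-peaks detected by a Pan–Tompkins-style
derivative-energy detector (5–25 Hz band-pass → differentiate → square →
150 ms integration → adaptive threshold, 200 ms refractory period, peak
refinement on the raw signal):

| feature | definition | fatigue trend |
|---|---|---|
| ECG_mean | mean RR interval (s) | ↓ (heart rate rises) |
| ECG_LF | RR-tachogram power in 0.04–0.15 Hz (s²) | ↑ |
| ECG_LF/HF | ratio to 0.15–0.40 Hz power | ↑ (sympathetic shift) |

The tachogram is cubic-interpolated to a uniform 4 Hz grid, mean-removed,
and its Welch PSD integrated over the bands. The HF band follows the
standard HRV convention. A vanishing HF power raises an error — the ratio
is never silently reported as 0. Spectral HRV features require at least 16
RR intervals, so windows must be ≳ 15 s at resting heart rates.

sEMG block (b = 4 × 2 channels):

| feature | definition | fatigue trend |
|---|---|---|
| IEMG | Σ\|x(k)\|/Fs (mV·s) | ↑ |
| RMS | √(Σx²/N) (mV) | ↑ |
| MPF | ∫f·P(f)df / ∫P(f)df (Hz) | ↓ |
| MF | f with ∫₀^f P df = ½∫P df (Hz) | ↓ |

All spectral features share one Welch PSD path (Hann, 1024-sample
segments, 50% overlap) so MPF, MF, LF and HF are mutually consistent; MF
interpolates linearly between bins. Windows are processed per 30 s
labelling period.

## The fused classifier

Features are z-scored with training-set statistics — they mix seconds, Hz
and mV·s, so unscaled fusion weights would be meaningless. A fusion
coefficient vector d (length 11, d_k ≥ 0, Σd_k = 11) multiplies the
standardized features elementwise; d_k acts as the trust placed in feature
k. Classification is a one-vs-one ensemble of three binary soft-margin
RBF-SVMs (kernel exp(−‖x−x'‖²/σ²), defaults C = 10, σ = √11), combined by
voting; vote ties are broken by the largest summed |decision value|, then
by the lowest class label — deterministic and independent of
support-vector order. The binary QP is solved by libsvm via scikit-learn;
tests verify each sub-model's decision function against an independent
SLSQP solution of the dual on small problems, and dual feasibility
(0 ≤ α ≤ C, Σαy = 0) on every trained sub-model.

A particle swarm optimizes d. Fitness of a candidate is the recognition
rate of an OVO-SVM retrained on the fused features of a stratified inner
split (70/30) carved out of the training set; the outer test set never
enters coefficient optimization. Updates follow the classic inertia form
with per-dimension uniform factors, velocities clamped to ±v_max = 2, and
every position mapped back onto the constraint set. Defaults: q = 50,
c1 = c2 = 0.5, ω = 0.8, expected fitness h_e = 0.95, ≤ 100 iterations.
`study_swarm_config()` provides the study-scale profile q = 2000 with the
same learning factors.

Two numerical choices matter here:

* **Constraint mapping mirrors, never clips.** Negative components are
  reflected about zero before rescaling to Σ = 11. Clipping to zero is an
  absorbing state: once a coordinate and the personal/global bests are all
  zero there, the velocity update can never resurrect it, and the swarm
  stalls on a boundary facet (observed as ~7% relative error on a
  known-optimum landscape in a sizeable fraction of runs; with mirroring
  the same landscape is recovered to machine precision).
* **Fitness averaging.** With a single inner split the fitness resolution
  is one eval sample (~2%) and its split-to-split noise ~3.5% SD, while
  the true generalization gain from downweighting a 3-feature noise block
  measures only +2.6–3.0%. A swarm given a single fixed split therefore
  optimizes split luck. `n_fitness_splits` averages the rate over several
  stratified splits (default 1 for speed; the weight-identification
  analysis uses 5).

## Synthetic data

Real labeled recordings of this protocol are not publicly available, so
the package ships a generator whose ground truth encodes the trends the
fatigue literature reports, at physiologically plausible magnitudes:

* **ECG**: a fixed PQRST template (sum of five Gaussians, P/T offsets
  scaled by the local RR) placed at beat times with
  RR(t) = rr_mean + lf_amp·sin(2π·0.1t) + hf_amp·sin(2π·0.25t). The
  deterministic sinusoidal modulation makes LF and HF band powers analytic
  (A²/2). Beat times snap to the sample grid, so stored R-peak ground
  truth is exactly recoverable.
* **sEMG**: white Gaussian noise shaped by a 4th-order Butterworth
  band-pass centered on a state-dependent characteristic frequency and
  rescaled to a state-dependent RMS.
* **Contaminants**: 50 Hz powerline, slow baseline wander, ECG
  bleed-through into the sEMG channels, wideband sensor noise.

State templates (defaults; no published per-state feature statistics exist
for this protocol, so these are package choices): mean RR 0.85/0.75/0.65 s, sEMG
RMS 0.10/0.14/0.20 mV, spectral center 120/105/90 Hz for
relaxed/transition/tired, with LF modulation growing and HF modulation
shrinking toward tiredness. Per-window Gaussian jitter (e.g. 0.04 s on
mean RR, 8 Hz on the spectral center) makes the transition state overlap
its neighbours, as real data do. A second, `complementary_profile`,
encodes modality-complementary information — ECG separates relaxed from
the rest, sEMG separates tired from the rest — which is the regime where
feature fusion has something to gain.

What the generator does **not** emulate: stochastic heart-rate
variability, beat morphology changes, motion artifacts, electrode-contact
drift, subject-level random effects, or true muscle synergy structure.
Passing tests therefore show the pipeline recovers structure it was built
to recover; they do not certify recognition rates on real recordings.

## Reference experiments and problem sizes

The packaged studies run at 100 windows per state (300 windows of 30 s,
the same window length as the labelling cadence; the full protocol scale
of 1200 windows, 400 per state, is available by configuration). Evaluation is Monte
Carlo cross-validation: 20 stratified 70/30 splits, classifiers retrained
per split, identical splits shared across compared models so differences
are not split noise. Batch studies apply low-pass + notch preprocessing
only: the synthetic contaminants are mild by design and the EMD stage,
whose value is for heavily contaminated recordings, is validated
separately on single windows.

On the complementary-information study the fused model reaches a mean
recognition rate near 98% against ~67–69% for either single modality —
the qualitative ordering (fused > sEMG-only, ECG-only) that motivates
fusion. In the weight-identification study (ECG block replaced by pure
standard-normal noise, 10 seeded refits with 5-split fitness), the mean
optimized weight on the informative block exceeds the noise block in
every run. Exact numbers for a given seed are computed by
`scripts/acceptance.py` and the test suite; none are hard-coded.

Baselines: BPNN (one hidden layer of 16 units, early stopping), KNN
(k = 5, Euclidean), LDA (pooled covariance), each behind a scaler on
unfused features. Their hyperparameters are conventional defaults, exposed
in configuration, and not tuned.

## Known limitations

* The SVM path targets desk-scale problems (hundreds of windows); no
  SMO-level performance work was done, and kernels other than RBF or more
  than three classes are out of scope.
* The adaptive notch assumes mains frequency within 49.5–50 Hz; 60 Hz
  mains requires changing the target frequencies in configuration.
* HRV features from 30 s windows are short-record estimates; LF resolution
  at 0.033 Hz is coarse, and per-window LF values are noisy (the
  classifier compensates by pooling windows).
* The single-split PSO fitness (default) is fast but noisy; use
  `n_fitness_splits ≥ 3` whenever the weights themselves, not only the
  final recognition rate, are of interest.
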