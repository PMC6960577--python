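# Methods

`affectflight` reimplements, as a tested library, a multimodal
psychophysiology analysis: recognizing the intensities of five emotions
(happy, sad, angry, surprised, scared) felt by a pilot during a simulated
flight, from heart rate (HR), galvanic skin response (GSR) and 8-channel
EEG, using facial-expression intensity traces as regression targets. The
original study's recordings are not publicly deposited, so the package
includes a first-class synthetic cohort generator that reproduces the
statistical structure the analysis assumes; every downstream stage is
exercised against cohorts with known latent ground truth.

## Synthetic flight cohorts

A flight session is a seven-task schedule (takeoff, climbing, cruise,
descent, approach, final approach, landing) over which a hidden 5-channel
emotion-intensity process evolves, plus four observed modalities coupled to
that process.

**Latent process.** Each intensity follows an Ornstein–Uhlenbeck process
reverting to the current task's mean vector (stationary sd 0.06, correlation
time 20 s), clipped to [0, 1]. The default task means give each task a
distinct dominant emotion — takeoff/landing → surprised, climbing → happy,
cruise → sad (monotony), descent/approach → angry (workload frustration),
final approach → scared. Task duration fractions (0.10/0.20/0.20/0.10/
0.10/0.20/0.10 of the session) were chosen jointly with the means so that
each of the five emotions is dominant in ≈20 % of flight time; the argmax
"major emotion" match statistic of an uninformative model then sits at the
1-in-5 chance level, which the zero-coupling control verifies.

**Observed modalities and coupling.** With arousal defined as the mean of
the scared and surprised intensities:

* HR (1 Hz, bpm): 75 bpm baseline + slow sinusoidal drift (amplitude 3 bpm,
  period 120 s) + white jitter whose sd is 0.5 bpm + 6 bpm × arousal, so
  short-term RR dispersion (Poincaré SD1) carries arousal.
* GSR (16 Hz, µS): 2 µS tonic level + slow drift + phasic events
  (instant rise, 2 s exponential decay, ~0.3 µS) with Poisson rate
  0.05 + 0.4 × arousal peaks/s, + 0.02 µS observation noise.
* EEG (500 Hz, µV, 8 channels, 10–20 labels Fp1…T8): broadband Gaussian
  noise (sd 8 µV) + a 12–30 Hz band-limited carrier whose RMS amplitude is
  2 µV + 6 µV × (w_c · e(t)); the fixed 8×5 mixing matrix gives the first
  five channels one emotion each and the last three mixtures, so the
  channel set jointly identifies all five intensities. At these defaults
  the in-band broadband floor is ≈2.1 µV RMS, giving a beta-band SNR that a
  10-s window power estimate (≈360 effective samples) resolves easily —
  this is the designed "high-SNR" regime.
* Face (30 Hz, intensities): the latent trace + truncated Gaussian noise
  (sd 0.03), clipped to [0, 1]. Window means of this trace are the
  regression targets.

Sampling rates mirror the device classes the protocol used (trend-memory
pulse oximeter, ~16 Hz skin-conductance logger, 500 Hz research EEG, video
frame rate); they are configurable because the original logging rates are
not stated. Sessions default to 300 s — long enough for 30 non-overlapping
10-s windows — a desk-scale choice, as the real session durations are also
unreported. Determinism: one master seed; per-session seeds are derived by
CRC-32 hashing of the session id mixed with the master seed, so sessions
are independent and cohorts bit-reproducible.

What the generator does *not* emulate: ECG/PPG waveform morphology, cortical
dipole geometry or volume conduction, EDA diffusion dynamics, facial-imaging
misclassification structure (its errors are i.i.d. truncated Gaussian, while
a real expression engine errs systematically). Passing recovery tests
therefore shows the pipeline correctly inverts the statistical structure it
assumes, not that it would reach the same accuracy on real recordings.

## Preprocessing

Per modality trace, in order: linear detrend → abrupt-change correction →
min-max normalization to [0, 1] (constant series map to 0.5) → for EEG only,
zero-phase 4th-order Butterworth band-pass at 12–30 Hz (beta band) →
windowing into 10-s non-overlapping windows (stride = length × (1 −
overlap); both configurable). Every stage preserves the sample count except
windowing. Windows keep each modality's native rate; no cross-modality
resampling is invented, features are rate-aware instead.

Abrupt-change correction replaces samples whose deviation from a 1-s rolling
median exceeds 5 robust standard deviations (1.4826 × rolling MAD). The MAD
collapses to zero on smooth or noise-free stretches and would flag natural
curvature, so the scale is floored at 10 % of the series' global MAD: a
deviation below about half the signal's robust amplitude is treated as
signal. This keeps the filter idempotent and inert on clean data.

Heart rate is special-cased: RR intervals (RR = 60000/HR ms) are undefined
on a min-max normalized trace, so each window also carries the despiked
bpm-scale HR from which the Poincaré descriptors are computed; the
statistical HR features use the normalized window like every other modality.

## Features (90 = 11 HR + 7 GSR + 9 × 8 EEG)

* Window statistics (population normalization): mean, median, sd, variance,
  RMS.
* Differential entropy: Freedman–Diaconis histogram plug-in, in nats
  (the log base being a convention choice); constant windows return a −30
  nat sentinel floor.
* Range: max − min by default; an endpoints mode |last − first| is provided
  because the two textual definitions of this feature disagree.
* GSR peak rate: prominent local maxima (prominence 0.05 in normalized
  units) per second.
* Wavelets (EEG): means of the level-4 `sym7` DWT approximation and detail
  coefficients. The transform is realized as a multilevel DWT rather than a
  CWT: the data are discrete and the named mother wavelet is a standard
  discrete Symlet.
* Poincaré descriptors (HR): with x = RR[:-1], y = RR[1:] and centroid
  (x̄, ȳ), SD1/SD2 are the root-mean-square distances to the two
  identity-line axes through the centroid (population mean, matching the
  printed definition), plus the centroid norm ‖(x̄, ȳ)‖ and ellipse area
  π·SD1·SD2.

The GSR block drops RMS to honour the stated seven-feature count (the
feature table marks eight rows for GSR; the stated count was taken as
authoritative and the dropped feature is configurable).

## SVD feature selection (50 = 6 HR + 4 GSR + 5 × 8 EEG)

Each modality block is column-centered and factorized A = U D V*. Features
are ranked by the norm of their loadings in the leading right singular
directions weighted by the singular values, and the top-count *original*
columns are kept (ties broken by original column order), preserving feature
identities. A projection mode (truncated scores U·D) is available behind a
flag because the source text supports both readings; selection is the
default since the retained counts are stated per modality. The SVD is
computed per block, not on the 90-wide matrix, for the same reason. In
cross-validation the reduction is fitted on training folds only.

## The MLP regressor

Forward: induced local field v_j = Σ w_ji x_i + b_j; hidden activation
sigmoid 1/(1+e^{−a·v}) (slope a ≥ 1, default 1) or ReLU; output sigmoid in
regression mode (five intensities in (0,1)) or softmax in classification
mode. Training minimizes the mean instantaneous error energy ξ = ½Σε²,
ε = d − y. Output deltas are δ_k = ε_k φ'(v_k); hidden deltas follow the
standard chain rule. The delta-rule update with momentum is
Δw(n) = α·Δw(n−1) + η·δ_k·y_j with y_j the *presynaptic* activation — the
printed update uses the postsynaptic symbol, which is taken as a typo for
the textbook rule — and the sigmoid-derivative factor is replaced by the
ReLU subgradient (0 at v = 0) in ReLU mode. `adam` (β₁ = 0.9, β₂ = 0.999,
ε = 1e−8) applies to the same gradients. Weights are Glorot-style scaled
uniform from a seed, biases zero; data order is fixed, so training is
reproducible given (seed, data). Both a vectorized full-batch mode
(default, used by the pipeline for speed) and a per-sample online mode
(the literal delta rule) are implemented; gradient correctness is verified
against central finite differences for both activations and output modes.

The pipeline default is a 2 × 10 hidden layout, adam at η = 0.01, 500
epochs full-batch — enough for the loss to plateau on cohort-scale
matrices (390 windows × 50 features); the 6000-epoch budget of the original
protocol is kept as the `NetworkSpec` default for the literal online mode.

Feature conditioning: the test matrix prescribes column centering; the
implementation additionally scales columns to unit variance (train-fold
statistics) because raw feature magnitudes span ~5 orders (RR centroid norm
in ms versus variances of normalized traces) and saturate sigmoid units.
Centering remains the documented step; unit scaling is a numerical
conditioning choice and can be disabled.

## Realtime Outliers Removal (RTOR)

Causal, per output channel: a sample that leaves the envelope of the last
N corrected samples by more than k robust standard deviations (1.4826 ×
batch MAD, floored at 10 % of the corrected stream's running range) is
replaced by the batch median; the first N samples are warm-up and always
pass through. Defaults N = 20, k = 4. The envelope-excess criterion (rather
than raw distance to the batch median) makes the filter idempotent and
keeps it from freezing on legitimate signal turns: a continuing trend
exceeds the envelope by one slope step, a network glitch by far more.

RTOR presumes a dense output stream in which artifacts are isolated
samples. The leave-one-flight-out harness emits one prediction per 10-s
window, so a 20-sample batch spans 200 s — longer than most task segments —
and would reject genuine emotional transitions; the evaluation harness
therefore does not apply RTOR by default, while the test-matrix runner
(which emulates the original protocol, where every run was
"recognition + RTOR") does.

## Evaluation

Leave-one-flight-out: one fold per session; feature selection and column
statistics are re-fitted on the training folds only; the held-out session's
windows are scored with per-emotion RMSE = √(Σ(ŷ−y)²/N) and
MAE = Σ|y−ŷ|/N (so MAE ≤ RMSE per fold by Jensen's inequality), plus the
major-emotion match accuracy: the fraction of windows whose argmax
predicted intensity equals the argmax target, ties broken by the fixed
emotion order on both sides. Reports carry per-fold values and
cohort means ± sd.

On the default 13-flight coupled cohort the pipeline recovers the latent
intensities (match accuracy ≈ 1.0, per-emotion RMSE ≈ 0.05–0.06 across
seeds); with all coupling gains zeroed the match accuracy falls to the
designed 0.2 chance level (±0.05 across seeds). These numbers are computed
by `scripts/acceptance.py` and the acceptance tests at run time.

## Known limitations

* The synthetic cohort shares one schedule across sessions; real flights
  differ in task timing, which would make cross-flight generalization
  harder than measured here.
* Raw-data mode (matrix tests 1–2) feeds each window's concatenated
  normalized samples to the network; at the default 500 Hz EEG rate this
  input is ~40 000 wide, so raw-mode runs are only practical on reduced
  configurations.
* Differential-entropy estimates on 10-sample HR windows are coarse; they
  are retained for structural fidelity of the feature set, not for their
  estimation quality.
* The per-flight error tables of the original study are not reproducible
  without its recordings and are out of scope.
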