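# Methods

`radarbp` implements a contactless blood-pressure (BP) estimation pipeline:
radar chest micro-vibrations are demodulated, filtered and windowed, a 1-D
residual network produces per-window preliminary systolic/diastolic
estimates (SBP/DBP), and a transformer refines those estimates over short
sequences of consecutive windows, exploiting both temporal continuity and
the physiological coupling between the two pressures.  Because no clinical
radar/BP dataset ships with the package, a seeded co-simulator generates
records with the statistical structure the pipeline assumes; everything
downstream is exercised and validated against it.

## The synthetic co-simulator

Each subject record consists of a chest-displacement signal sampled at
2000 Hz (wrapped into radar I/Q phase via `i = cos(4*pi*d/lambda)`,
`q = sin(4*pi*d/lambda)`, `lambda` = 12.5 mm for a 24 GHz carrier) and an
arterial pressure waveform at 200 Hz, synchronized on a common clock
(optionally offset by `t0_offset` for alignment experiments).

**Beats.** Heart rate follows a reflected random walk inside `hr_range`
(default 55-95 bpm).  The recording starts systolic-peak-aligned: the first
systolic peak is at t = 0.  This is the natural "recording begins at an
arbitrary beat phase" convention and makes the windowing arithmetic exact
(a 60 s record tiles into exactly 30 non-overlapping 2 s windows).

**Pressures.** Per-beat SBP and DBP are mean-reverting AR(1) processes
around a subject baseline, built from a shared latent component plus
independent ones.  The shared-component weight (`sbp_dbp_corr`, default
0.7) equals the stationary SBP-DBP level correlation, mirroring the strong
systolic-diastolic coupling seen clinically (reported correlations around
0.7).  The innovation scale is `bp_drift_sd` (default 1.2 mmHg/beat) with a
reversion timescale of ~20 beats; values are reflected into the configured
ranges, and DBP is capped at SBP − 10 mmHg.  With `bp_drift_sd = 0` the
pressures are constant — the degenerate case used by several tests.

**Waveform.** Between consecutive peaks the pressure decays exponentially
from SBP to DBP (a shifted exponential that reaches DBP exactly at the
trough, placed at 0.85 of the beat interval) and then rises linearly into
the next peak.  Waveform extrema therefore match the per-beat truth to the
200 Hz sampling discretization.

**Displacement.** Respiration is a sinusoid (default 0.25 Hz, 1.5 mm;
zeroed in the `apnea` scenario).  Each beat adds a raised-cosine pulse
whose amplitude is `pulse_amp_gain x (SBP − DBP)` plus a smaller
reflected-wave bump.  Because every window is later L2-normalized —
which discards absolute amplitude — the pulse *morphology* also encodes
the pressures, mimicking pressure-dependent arterial stiffness: higher SBP
narrows the primary upstroke and pulls the reflected wave earlier (faster
pulse-wave velocity), and the reflected wave's relative amplitude grows
with DBP (augmentation).  Gaussian noise of SD `noise_sd` is added to the
displacement.  `valsalva`/`tilt` scenarios inject a ±20 mmHg triangular
ramp over the middle third of the record — a deliberate caricature of the
maneuvers, not a hemodynamic model.

**What the simulator does not emulate.** Radar hardware artifacts (I/Q
imbalance, DC offsets, multipath), body motion, real CNAP reference noise,
missing labels, and genuine beat-to-beat waveform variability.  Passing the
synthetic study shows the pipeline is implemented correctly and can recover
BP when the radar signal carries it — it does not certify clinical accuracy
on real recordings.

## Preprocessing

Fixed order: arctangent demodulation (unwrapped `atan2(Q, I)` scaled by
`lambda/(4*pi)`, first sample referenced to zero) → zero-phase band-pass →
polyphase resampling to 150 Hz → guard-interval trim → per-window
detrending → derivative channel → per-channel L2 normalization.

The band-pass is a 4th-order Butterworth (0.5-15 Hz) applied
forward-backward (bidirectional), giving zero phase and the squared
magnitude response; it is designed in second-order sections because the
0.5 Hz edge sits ~3.5 decades below the 2000 Hz rate, where the
transfer-function form is numerically singular.  Odd-reflection padding of
3x the filter length handles the edges.  2000 → 150 Hz is the non-integer
ratio 40/3, handled by rational polyphase resampling with anti-aliasing.
`guard_s` (default 0.25 s) trims each record edge; the intent of guard
intervals against spectral leakage is under-specified upstream, so the
trim length is exposed in the config.

Detrending removes the ordinary-least-squares line over the window, with
the sample index as regressor (slope units cancel in the residual).  The
second derivative channel uses the centred scheme
`y''[n] = (y[n+1] − 2 y[n] + y[n−1]) / Ts²`, exact for quadratics; orders
1 and 3 (ablation inputs) iterate the binomial first-difference kernel,
which carries a half-sample alignment per application — immaterial after
normalization, and the test suite checks the composition identity up to
that known one-sample shift.  Edge samples are replicate-padded so window
length is preserved.

## Windowing and labels

Systolic peaks are detected as local maxima with ≥ 10 mmHg prominence and
≥ 0.33 s spacing (a peak at the very first sample counts; a final-sample
maximum does not, having no beat behind it).  The diastolic trough is the
minimum between consecutive peaks; the final beat uses the minimum to the
record end and is valid only if at least the minimum spacing remains.
Pressures outside (40, 180) mmHg mark a beat as an outlier.

The first valid peak anchors a grid of non-overlapping windows (default
2 s).  A window is emitted only if every beat whose peak falls inside it
is valid and at least one does; its labels are the means of the in-window
beat SBPs and DBPs (the least-variance unbiased per-window aggregate).
Each window carries two L2-normalized channels: the detrended
micro-vibration signal and its derivative.  A conservation ledger
(`tiled = emitted + dropped`) is kept per record.

Splits default to window-level 65/15/20 with a seeded shuffle;
subject-level splitting (all of a subject's windows in one partition) is a
first-class alternative, since "no overlap between groups" is ambiguous
between the two readings.

## The dual-stage regressor

Both stages are built on a small reverse-mode automatic-differentiation
engine over numpy arrays (`radarbp.nn`): broadcast arithmetic, batched
matmul, 1-D convolution/max-pooling, ReLU, reductions and shape ops, with
softmax, batch/layer normalization and attention as composites.  Float64
throughout; every closed-form oracle in the tests is checked against it,
and conv/pool/attention gradients are verified against central
differences.

**Stage 1** is a 1-D adaptation of an 18-layer residual network: stem
convolution (kernel 7, stride 2), max-pool, four stages of basic blocks
(two 3-tap convolutions with batch norm around an identity skip,
`y = F(x) + x`; 1x1 projection when shape changes), global average
pooling.  A shared trunk (a dual-trunk mode exists behind a flag) feeds
two branch heads that produce the pressure-specific feature vectors `F_S`,
`F_D` (length `feature_dim`) and dense preliminary predictions.
Predictions are de-normalized as `mean + sd x raw` with the statistics
frozen from the training labels, so the network regresses an O(1)
quantity — without this the output head cannot traverse tens of mmHg in a
short optimization budget.

**Fusion** forms `X_S = [F_S, z(y_D)]` and `X_D = [F_D, z(y_S)]` — each
pressure's features are extended with the *other* pressure's preliminary
estimate, exploiting the SBP-DBP coupling.  The appended estimate is
z-scored with the stage-1 output statistics: dividing by a fixed 200 mmHg
would match its magnitude to the unit-norm features but leave its
informative variance ~4x10⁻⁴, effectively invisible to a short fit.

**Stage 2** is a pair of per-pressure transformer encoder-decoders over
sequences of T = 8 consecutive same-subject windows (non-overlapping
chunks in time order; within each split, so partitions stay disjoint —
leftover windows keep their stage-1 estimate).  Keeping the streams
separate is what makes the fusion ablation meaningful: with a single
concatenated stream the encoder would see both feature sets regardless.
Each encoder embeds its stream's fused vectors, adds sine-cosine
positional encodings, and applies post-norm blocks (multi-head attention,
then a two-layer ReLU feed-forward, each wrapped in residual + layer
normalization).  The decoder input is a learned start token followed by
the z-scored preliminary estimates shifted one position right (so position
t conditions only on estimates before t; a causal mask enforces this in
self-attention — a perturbation probe in the tests verifies it); in fusion
mode the decoder tokens carry both pressures' estimates, otherwise only
the stream's own.  Cross-attention reads the encoder output, and a
near-zero-initialized head emits a residual correction added to the
stage-1 estimate — stage 2 starts as the identity refinement and can only
build on stage 1.  Teacher forcing with ground-truth labels is disabled:
decoder inputs are model estimates, never labels, so no label leakage.

Unstated architectural sizes are configuration defaults, not claims:
`d_model = 64`, 4 heads, 2 encoder + 2 decoder layers, `d_ff = 128`,
`feature_dim = 512` (the scaled-down study uses 64/32/64).

## Training regime

Both stages minimize the summed Pseudo-Huber loss of the SBP and DBP
errors, `delta² (sqrt(1 + (a/delta)²) − 1)` with `delta = 5` mmHg (the
scale of the AAMI mean-error bound; quadratic below it, linear above),
unweighted between the two pressures.  Optimization is Adam with decoupled
weight decay (lr 0.001, decay 0.002), batch 32 for stage 1 and 4 for
stage 2, up to 60 epochs.  The learning rate halves when validation loss
fails to improve for 5 consecutive epochs (with a constant validation
stream the first halving lands at the end of epoch 6), and early stopping
(patience 10) plus best-validation checkpointing — which includes the
untrained initial state, so training can never return a model that
validates worse than where it started — guard generalization.  Stage-1
weights are frozen during stage-2 training.  The test split touches no
fitting or scheduling decision.

## Clinical validation statistics

* ME = mean(y − ŷ), MAE, RMSE, MRE (percent of reference), and the sample
  SD (n−1) of the errors; `RMSE² = ME² + (n−1)/n·SD²` is asserted as an
  internal consistency check.
* BHS grading: cumulative percentages of |error| strictly below 5/10/15
  mmHg, compared with ≥ against A = 60/85/95, B = 50/75/90, C = 40/65/85;
  the best grade whose three thresholds all hold.  One reported
  cumulative triple (51.20, 77.58, 88.93), sometimes described as
  B-compliant, fails B's 90% bound at <15 mmHg; this grader returns C and
  the discrepancy is pinned in a test rather than silently matched.
* AAMI: pass iff |ME| ≤ 5 mmHg (inclusive) and SD < 8 mmHg (exclusive).
* Bland-Altman: differences are predicted − reference; limits of agreement
  are mean ± 1.96 x sample SD.
* Regression diagnostics: Pearson r, R², and the OLS line of predictions
  on reference values.

## The scaled-down study

`radarbp.pipeline.scaled_study_config` pins the synthetic experiment the
acceptance script and the end-to-end test run: 10 subjects x 5 minutes,
strong BP-to-pulse coupling (`pulse_amp_gain = 0.03` mm/mmHg,
`noise_sd = 0.02` mm), reduced widths (stem 8 → 64-dim features,
`d_model = 32`, `d_ff = 64`), 10 epochs — sized so the full three-variant,
three-seed comparison (stage-1 only, stage-1 + transformer, full fusion)
trains in a few minutes on one CPU.  On this study the trained cascade
beats the mean-predictor baseline for both pressures and the seed-averaged
test MAE is ordered stage-1-only ≥ stage-1+transformer ≥ full-fusion.
The absolute errors reported on synthetic data are not comparable to
clinical accuracies on real radar recordings.

## Numerical choices and degenerate inputs

* TLCC uses overlap truncation (each lag's coefficient is a genuine
  Pearson on the shared support); ties in the best lag break toward the
  smallest |lag|.
* Zero-magnitude I/Q samples, zero-variance correlation inputs, zero
  vectors under L2 normalization, windows longer than the record, and
  empty splits raise `ValueError` rather than returning NaNs; flat
  pressure signals yield an empty beat list.
* All stochastic steps (simulation, shuffling, splitting, weight
  initialization) draw from explicit `numpy` generators seeded from the
  configuration; identical seeds reproduce results bit-for-bit.

## Known limitations

* The simulator's morphology-pressure link is a stylized stand-in for real
  hemodynamics; models trained on it do not transfer to real radar data.
* The transformer sequence construction chunks each split's windows in
  time order, so sequences may span temporal gaps where windows were
  dropped or assigned to other splits.
* The numpy NN stack is single-threaded and sized for desk-scale
  experiments, not for training at clinical-dataset scale.
* Beat detection assumes CNAP-like waveforms with ≥ 10 mmHg pulse
  prominence; heavily damped reference waveforms would need different
  peak parameters.
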