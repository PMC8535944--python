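# Methods

This note records the models, conventions and numerical choices behind
`heartkit`, what the synthetic generator does and does not emulate, and the
limitations a user should know before trusting a green test suite.

## Signal model and preprocessing

A phonocardiogram is treated as a quasi-periodic sequence of two transient
valve sounds per cardiac cycle: S1 opens systole, S2 ends it; murmurs add
band-limited noise over the systolic interval, extrasystoles perturb the
inter-beat grid.  All processing after ingestion happens at a working rate
of 2 kHz — the primary heart-sound band is roughly 25–120 Hz and murmur
energy rarely exceeds several hundred Hz, so 2 kHz retains everything of
clinical interest at 1/22 of a typical 44.1 kHz recording.

Denoising uses a 4th-order Butterworth band-pass, 25–600 Hz, applied
zero-phase (forward–backward) at the **native** rate so it doubles as an
anti-alias guard before the polyphase resampler.  The band edges are a
documented choice, not an external constant: 25 Hz removes chest-movement
rumble without touching S1, and 600 Hz keeps murmur content while rejecting
hiss.  Amplitude normalization divides by max |s| (peak convention), which
makes envelope statistics comparable across recordings; silent input is
rejected rather than propagated as NaNs.

## Heart-cycle segmentation

**Wavelet stage.**  The signal is decomposed to 5 levels with a Daubechies-6
filter (computed in-package by spectral factorization of the binomial
polynomial; the transform is periodized and exactly orthogonal, so
decompose→reconstruct is the identity to ~1e−15 RMS).  Every band is
thresholded with its own adaptive threshold thr = μ(|C|) + f·σ(|C|), f = 1
by default, population σ.  The default keeps coefficients strictly **above**
the threshold (hard thresholding): the low-amplitude coefficient bulk is the
noise floor, the salient tail is the heart-sound structure.  The inverted
rule (keep below) is available as `keep_mode="below"` but measurably removes
the transients instead of the noise — on denoised synthetic input it raises
the spectral centroid from ~210 Hz to ~300 Hz and degrades beat recovery —
so it is not the default.

**Envelope.**  Frame-wise Shannon energy SE = −(1/N) Σ e_j log e_j with
e_j = s_j² and 0·log 0 := 0 (raw samples can be negative, so the energy
convention is required for the logarithm to be defined).  Frames are 40
samples (20 ms) with hop 20 (10 ms): long enough to integrate one S1/S2
lobe, short enough to resolve it.  The envelope is standardized to zero
mean / unit variance; this emphasizes *medium* amplitudes — a property
worth remembering: the softer S2 often out-peaks S1 on this scale.

**Period.**  The unbiased autocorrelation r(τ) = (1/(L−τ)) Σ x_t x_{t+τ} of
the standardized envelope is searched in a physiological lag window of
0.4–1.6 s (37–150 bpm).  Two corrections are applied to the raw arg-max:

* the 1/(L−τ) normalization inflates large lags, and frame-phase
  quantization (a period is rarely an integer number of hops) suppresses the
  fundamental peak, so the global maximum frequently lands on 2× or 3× the
  true period;
* each subharmonic candidate τ*/k (k = 2,3,4, refined to the local peak) is
  therefore scored by its **harmonic sum** — the mean autocorrelation near
  its first three multiples.  A true period scores high at every multiple,
  whereas a spurious candidate such as the diastolic S2→S1 spacing hits the
  anti-phase trough at its double.  The smallest candidate within 60 % of
  the best score wins.  On 50 seeded synthetic recordings (50–140 bpm,
  SNR 10–25 dB) this yields a median relative period error of ~0.4 % and
  beat-count recovery within ±1 for ≥ 95 % of recordings.

The reported confidence is r(τ*)/r(0) clipped to [0,1] — a crude
periodicity score, not a calibrated probability.

**Cutting.**  Envelope peaks above 0 mark S1/S2 lobes.  One anchor per cycle
is chosen by the physiological asymmetry systole < diastole: among adjacent
lobes, the one followed by a short gap (< period/2) starts a cycle.  The
acoustic onset is the centroid of the anchor lobe (bounded to ±0.15 period
so a merged S2 lobe cannot drag it) minus an S1 half-duration of 45 ms,
dated at frame centers.  With the generator's textbook S1 timing this
recovers onsets to ~±12 ms at 75 bpm and ~±30 ms at extreme rates.  Segments
span [onset, onset + period), truncated at the next onset (segments are
disjoint by construction); a trailing fragment shorter than half a period is
dropped.

## MFCC features

Frames of 1024 samples (Hamming window, hop 512) go through: DFT magnitude →
natural log floored at 1e−10 → 26-filter triangular mel bank spanning
0–Nyquist (unit-peak triangles, centers equally spaced in mel) → orthonormal
DCT-II → first 13 coefficients.  Note the ordering: the log is applied to
the magnitude spectrum *before* the filterbank smoothing.  This deviates
from the common filterbank-then-log recipe and is kept deliberately as this
pipeline's definition of the feature; the dedicated oracle test pins the
exact chain.  At 2 kHz a 1024-sample window is 512 ms — long relative to a
cycle, so a segment yields only a handful of frames; short segments are
zero-padded to one window rather than rejected.

Spectrogram images map coefficient values linearly min→0, max→255, apply the
fixed `viridis` colormap (time on x, coefficient index on y, c0 at the
bottom) and resize with nearest-neighbour to 640×480×3.  Identical matrices
produce byte-identical PNGs; a constant matrix maps to uniform mid-gray by
definition.  The per-segment summary vector is the concatenation of
per-coefficient means and population standard deviations (26 dims for the
default 13 coefficients).

## Segment selection (GMM + EM)

Per-class pools of summary vectors are z-scored per dimension (cepstral
coefficient scales differ by orders of magnitude) and clustered with a
two-component Gaussian mixture with diagonal covariances — full covariances
would be ill-conditioned at typical segment counts.  EM uses the standard
estimation step t(i,k) ∝ π_k N(x_i | μ_k, σ²_k) (computed in log space) and
the closed-form maximization updates; convergence at |Δ log L| < 1e−6 or 200
iterations; k-means++ seeding with 5 restarts keeping the best final
log-likelihood.  Two numerical guards:

* `reg_covar = 1e−6` is added to every variance in the M-step.  The mixture
  likelihood is otherwise unbounded (a component can shrink onto one point);
  the regularizer bounds it without visibly biasing well-separated fits.
* a component whose variance still reaches the 1e−9 floor is re-seeded once;
  a second collapse raises an error rather than returning garbage.

Selection keeps the larger hard-assigned cluster; an exact size tie is
broken toward the cluster whose own component assigns its members the higher
total log-likelihood.  The accounting identity |kept| + |ignored| = n holds
for every input.  On synthetic pools of 80 clean + 20 heavily corrupted
(SNR 0 dB) segments the ignored set is essentially exactly the corrupted
subset across seeds.

## Classification protocol

Folds are stratified by class **and grouped by recording**: cycles of one
recording never straddle train/validation, because neighbouring cycles of
the same recording are nearly duplicates and would leak.  Per class c the
one-vs-rest metrics are TPR = TP/(TP+FN), PPV = TP/(TP+FP),
TNR = TN/(TN+FP), accuracy = (TP+TN)/total; a ratio with a zero denominator
is reported as absent (None) and skipped in averages, never coerced to 0.
"Folds avg" averages each metric over folds per class; "Classes avg" then
averages over classes (unweighted in both steps).  Plain multiclass accuracy
(trace/total) is reported separately.

Training defaults mirror a fine-tuning setup: SGD, learning rate 1e−4,
momentum 0 (the conventional framework default), batch size 5, 100 epochs,
3 folds.  The logistic baseline ignores the SGD knobs (scikit-learn lbfgs;
deterministic).  The numpy `small_cnn` backend — one 3×3 conv layer, ReLU,
global average pooling, two dense layers, softmax — is a desk-scale stand-in
for the pool-dense-dense-softmax head used on large pretrained trunks; its
hidden sizes default to 32/16 so that CPU training is feasible, and it is
deterministic given a seed.  An `external_pretrained` adapter slot exists
but raises: ImageNet-scale trunks and GPU fine-tuning are out of scope here.

## Synthetic generator: what it emulates, what it does not

One cycle = a Gaussian-windowed 40 Hz burst of 70 ms (S1) at phase 0 plus a
0.7-amplitude 60 Hz burst of 50 ms (S2) at 0.35 of the period — textbook
first/second heart-sound frequencies and systole fraction.  Murmur class:
unit-RMS noise band-passed to 120–400 Hz, gated over the S1→S2 interval,
amplitude 0.4 of S1.  Extrasystole class: with probability 0.25 per beat the
next beat arrives after 0.6 of the normal interval (the premature beat is
the one *after* the short coupling interval, and is labeled as such).  White
noise is added at a configurable SNR measured against the clean mixture;
corpus generation jitters bpm in [60, 110] and SNR in [15, 25] dB per
recording.  All randomness flows from one seed.

Not emulated: respiration and friction artifacts, S3/S4 sounds, diastolic
murmurs, amplitude variation between beats, sensor transfer functions, and
compensatory pauses after extrasystoles.  A green segmentation or selection
test therefore establishes correctness of the *algorithmic chain* on signals
with the stated structure — not clinical performance on hospital recordings.

## Pipeline and reproducibility

The orchestrator runs denoise → resample → normalize → wavelet → envelope →
period → cut → MFCC → select → train/evaluate, persists every intermediate
(segments CSV, features CSV, selection JSON, report JSON/CSV) and writes a
JSON-lines log with per-stage counts; kept + ignored always equals segments
produced.  A stage failure aborts with the stage name and item id.  One
global seed fans out to fixed per-stage offsets (selection +1000, folds
+2000, training +3000), so a single integer reproduces the entire run; with
the deterministic backends the report JSON is byte-identical across runs.

## Known limitations

* Segment onsets are envelope-derived; at heart rates above ~120 bpm the S1
  and S2 lobes begin to merge at the default 20 ms frames and onset jitter
  grows to a few tens of milliseconds.
* The UACF assumes one dominant period; heavy bigeminy (every second beat
  premature) can legitimately halve or double the detected cycle.
* Per-cycle features barely encode rhythm, so extrasystole recognition from
  single cycles is intrinsically weak — visible in the worked example, where
  extrasystole-vs-normal confusion dominates the error.
* The mel filterbank spans 0–1000 Hz at the working rate; recordings kept at
  other rates shift the filter centers accordingly.
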