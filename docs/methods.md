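# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the behavior of the synthetic-data generators, and
the numerical and design choices made where the procedure was genuinely
open.

## Cry acoustics

### Segmentation

Cry recordings made in clinical settings mix expiratory cry, inspiratory
(ingressive) sounds, other vocalizations and room noise. The segmenter is a
frame-level classifier over the same 25-ms/12.5-ms framing the pitch stage
uses, with three features per frame:

- **short-time RMS energy** — frames below `max(1e-4, 0.05 × the 95th
  percentile of frame RMS)` are silence and belong to no segment;
- **harmonicity** — the minimum of the cumulative-mean-normalized
  difference function over the 200–700 Hz lag band; frames at or below 0.3
  are voiced and labeled *expiratory*;
- **mid-band spectral concentration** — among unvoiced sounding frames,
  those with more than 55% of their spectral energy in 2–6 kHz are labeled
  *inspiratory* (breathy ingressive noise is band-concentrated), the rest
  *residual* (broadband noise and other sounds spread energy across the
  full bandwidth, so their 2–6 kHz fraction stays low).

Labels are median-filtered (width 5 frames ≈ 62 ms) and runs shorter than
100 ms are dropped. Segment boundaries are taken at frame starts, so a
boundary is accurate to roughly the frame length (25 ms); the suite checks
recovery of generator truth within ±50 ms. This is an intentionally simple,
fully documented stand-in for trained HMM-style segmenters: it reproduces
the contract (extraction of expiratory phases) rather than any particular
trained model. An HMM smoothing layer over the same frame features would be
a drop-in alternative.

### Pitch estimation

YIN over each expiratory phase:

1. frames of `round(25 ms · rate)` samples, hop `round(12.5 ms · rate)`,
   trailing partial frames discarded (no zero-padding — padded frames would
   bias the difference function at phase edges);
2. squared difference function `d(τ) = Σ_{j<N} (x[j] − x[j+τ])²` with a
   fixed integration window `N = frame_len − τ_max`, computed by FFT
   cross-correlation (a brute-force oracle pins this down in the tests);
3. cumulative-mean normalization `d′(τ) = d(τ)·τ / Σ_{j≤τ} d(j)`,
   `d′(0) = 1`; a constant frame (zero cumulative sum) normalizes to 1,
   i.e. maximally aperiodic;
4. lag search restricted to `[rate/700, rate/200]`; the first lag with
   `d′ < 0.3` is taken and walked downhill to its local minimum, otherwise
   the global minimum in the band; parabolic interpolation refines the lag
   (and the minimum value) to sub-sample precision;
5. `F0 = rate / lag`; the frame's aperiodicity `Ap` is the (interpolated)
   `d′` minimum, clipped at 0. Frames with `Ap > 0.3` carry no estimate.

The absolute-threshold/first-dip rule is what suppresses octave-down
errors; restricting the lag band to 200–700 Hz suppresses the rest. The
suite requires, on clean harmonic input at 250–650 Hz, per-phase means
within 1% of truth and no frame within 2% of half or double the true F0.

The aperiodicity threshold plays its usual double role (dip-picking
threshold and frame-retention tolerance); both default to 0.3.

### Phase filtering and aggregation

Filters are applied strictly as stated: keep phases with duration **>**
500 ms; drop phases with inharmonic fraction **>** 0.7 (evaluated over all
frames of the segmented phase); of the survivors, in temporal order, keep
the first five. "First five" counts phases *after* filtering — this
maximizes usable data and matches the reading "the available scorable
expiratory phases". Per-phase SD is the sample SD (n−1) over retained
frames, computed after the aperiodicity-based frame discard. Fewer than
three surviving phases makes the recording unusable (the error carries the
count); three or four phases aggregate over what is available.

Stereo recordings are mixed to mono by the channel mean before analysis —
deterministic and symmetric; recordings at other sampling rates are
analyzed at their native rate (all parameters are specified in
milliseconds/Hz, not samples).

## Gaze attention

Coordinates are degrees of visual angle in a screen-centered frame (x
rightward, y upward); time is milliseconds from trial start; AOI
containment uses closed rectangle bounds. The scorer works directly on the
raw 300-Hz sample stream; no fixation filtering or smoothing is applied.

Per trial, with lateral (target/distractor) onset `T`:

- **shift** — the first valid sample inside the lateral AOI after `T`;
- **analysis period** — trial start to the shift, or to `T + 1000 ms` if
  none;
- **gap rule** — missing data are runs of invalid samples (or holes in the
  timestamp stream); a run is measured between the valid timestamps
  bracketing it; any run > 200 ms inside the analysis period invalidates
  the trial. Gaps after the analysis period are irrelevant by construction;
- **transition rule** — invalid samples between the last central-AOI
  sample and the shift sample invalidate the trial (the saccade happened
  inside missing data);
- **fixation rule** — among valid pre-shift samples, the fraction inside
  the central AOI must exceed 0.7. The fraction is computed over valid
  samples, not wall-clock time, so gaps are not double-penalized; the
  pre-shift interval starts at trial start (central-stimulus onset);
- **off-screen rule** — valid samples between leaving the central AOI and
  entering the lateral AOI that fall outside the screen rectangle (default
  ±13.5° × ±10.5°, configurable) exclude the trial.

Orienting SRT = first lateral-AOI sample time − `T`, accepted in
[150, 1000] ms (`too_early`/`too_late` otherwise). The disengagement
saccade time `x` = last central-AOI sample before the shift − `T`; the two
definitions differ deliberately, each matching its task's convention. A
disengagement trial whose first shift lands after the 1000-ms window end is
scored as a no-shift trial at `x = 1000` — the window end is the last
measured time point of the central stimulus, so a later saccade is
indistinguishable from none within the analysis period.

Dwell contribution: `1 − (window_end − x)/norm_range` with defaults
1000/850; the condition index is the mean over that condition's scorable
trials (valid shifts plus no-shift trials at `x = 1000`, ≥ 3 required); the
participant index is the unweighted mean over the three conditions (not
pooled over trials). Orienting inclusion needs ≥ 4 scorable trials. Window
parameters are configuration, so cohort variants (e.g. a 2000-ms lateral
availability) are profiles, not code branches; the 1000/850 window is the
default for both cohorts.

## Cohort statistics

- Two-sample comparisons use Student's pooled-variance *t*
  (df = n₁ + n₂ − 2), not Welch — the convention the reported degrees of
  freedom follow. `summary_t_test` applies identical formulas to (n, mean,
  SD) summaries, so a printed descriptive table can drive the test; the
  suite checks the raw-data and summary routes agree to 1e-10.
- Cohen's *d* divides by a pooled SD with denominator n₁ + n₂ by default
  (this is what reproduces effect sizes published alongside these pooled
  *t*-tests), switchable to n₁ + n₂ − 2.
- Pearson correlations are two-tailed, *p* from the exact *t* transform
  with df = n − 2 (delegated to `scipy.stats.pearsonr`; a hand-formula
  oracle pins it in the tests). Pairs with a missing member are dropped
  pairwise per analysis, so per-cell n's differ.
- The Kolmogorov–Smirnov normality check (against a normal at the sample's
  mean/SD) is reported for diagnostics only; nothing is gated on it.
- The correlation table crosses cohort × subgroup (all; Tampere
  beginning-of-bout; Cape Town SSRI-excluded) × {F0, F0var} × {orienting,
  dwell}; alpha is 0.05 with no multiple-comparison correction; cells with
  fewer than 3 complete pairs are marked not computable.

## Synthetic data

**Cry** (`synth_cry`): harmonic additive synthesis — eight harmonics with
geometrically decaying amplitudes following an instantaneous-F0 contour,
20-ms cosine onset/offset ramps, phases separated by silent pauses,
optional 2–6 kHz band-limited inspiratory noise bursts, and white noise at
a configurable SNR. The contour is `base + A·sin(2πft)` with an integer
number of cycles per phase and `A = sd·√2`, so the contour's population SD
equals the requested within-phase SD exactly, making F0var recovery
quantitative. Per-phase base F0 is drawn from a normal (defaults: mean
463.45 Hz, SD 62.52 Hz — the cohort-level descriptives) clipped to
250–650 Hz so every draw stays analyzable; the default within-phase
contour SD (≈16 Hz) is deliberately below the cohort-level F0var of
~65 Hz, which includes estimator and biological variance a smooth drift
does not model. Not modeled: formants, subharmonics/biphonation, vibrato
jitter/shimmer, reverberation — so passing tests demonstrate correctness of
the pipeline's arithmetic and filtering on controllable signals, not
robustness to every real-world cry pathology.

**Gaze** (`synth_gaze`): per trial, 300-Hz samples fixate the central AOI
with Gaussian scatter (default 0.4°), then step to the lateral AOI at a
latency drawn from a normal (defaults 421.36/53.41 ms) truncated to
160–990 ms so the realized shift stays inside the scoring window;
disengagement trials are no-shift with probability `p_no_shift`. Injected
gaps mark a run of samples invalid starting at 300 ms (inside the analysis
period). Saccade kinematics (velocity profiles, under/overshoot), drift,
and blink artifacts are not modeled; scorer recovery is therefore exact up
to the sampling interval (≈3.33 ms), which is what the tests assert.

**Cohorts** (`synth_cohort`): a Gaussian copula — latent multivariate
normal with the specified correlation matrix (eigendecomposition handles
PSD-singular cases), scaled to the specified marginal means/SDs. Dwell
indices are clipped to [0, 1]; the default parameterizations keep the mean
≥ 1.5 SDs from the bounds so the clipping bias is small (visible only as a
slight attenuation of planted correlations involving dwell).
`tampere_cohort_spec` / `cape_town_cohort_spec` carry the two cohorts'
published marginals, cross-correlations, subgroup fractions and sample
sizes as defaults.

## Problem sizes and numerics

The test suite and examples run simulations at the scale that makes their
statistical tolerances meaningful: F0 recovery uses 3-phase recordings per
frequency; correlation recovery uses n = 10 000 participants (tolerance
0.03 on r); the null false-positive rate uses 500 replicates at n = 50
(expected band 3–8% at alpha 0.05). All generators take explicit seeds and
are bit-deterministic; the pipeline writes a manifest (config hash, seed,
version, row counts) sufficient to reproduce a run.

Numerical details worth knowing: the difference function is evaluated over
a fixed integration window so all lags average the same number of terms;
parabolic refinement is clamped to ±0.5 lag and falls back to the integer
lag for non-convex neighborhoods; refined F0 is clipped into the 200–700 Hz
band; threshold comparisons are strict as documented (Ap **>** 0.3
discards, inharmonic fraction **>** 0.7 excludes, duration **>** 500 ms
includes, fixation **>** 0.7 passes). Degenerate inputs raise typed errors
(`UnusableRecordingError`, `InsufficientDataError`,
`DegenerateVarianceError`) rather than returning silent NaNs, except in the
batch path, where unusable recordings are flagged rows.

## Known limitations

- The segmenter is heuristic; heavily reverberant or low-SNR recordings
  will misplace boundaries more than the ±50 ms the generator-based tests
  demonstrate.
- F0var conflates estimator noise with physiological variability at low
  SNR, as any frame-wise SD does.
- The dwell index's no-shift convention makes it right-censored at 1;
  cohorts with many no-shift trials compress toward the ceiling.
- Cohort simulation uses normal marginals; real F0var distributions are
  right-skewed, so simulated type-I behavior is exact only under
  normality.
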