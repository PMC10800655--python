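# Methods

`emophysio` implements an end-to-end analysis of multimodal physiological
responses to affective stimulation: a three-phase protocol simulator, six
per-signal feature extractors (57 features total), a box-overlap feature
selection algorithm (the "Square Method"), and a subject-stratified
classification benchmark for the four emotion classes of Russell's
circumplex. Because no public recording set exists for this protocol, the
package ships a seeded synthetic generator whose planted parameters define
the ground truth every extractor is tested against.

## Protocol model

Each subject completes three randomized phases (images, sounds, combined),
each consisting of a resting baseline (default 300 s) followed by four 90 s
sessions of strictly increasing arousal (A1..A4). A session holds six 15 s
stimuli: the first three at low valence, the last three at high valence, so
each session splits into two 45 s analysis windows. Crossing the extreme
arousal sessions with the valence halves yields the four classes A1-LV
(sadness), A1-HV (relaxation), A4-LV (fear/anger), A4-HV (happiness); the
intermediate sessions A2/A3 are present in the timeline but unlabeled and
excluded from analysis. Per subject this gives 24 windows, 12 labeled; a
22-subject cohort gives 264 labeled observations, 88 per phase. Timing uses
half-open intervals `[t_start, t_end)` in seconds from phase start, which
makes sample slicing unambiguous at any rate. The inter-session gap defaults
to 0 s and is configurable; the protocol's printed total duration is not
enforced because it does not decompose exactly from the stated segment
durations.

## Synthetic recordings

The generator injects class effects only through the quantities the
extractors measure, not through physiological forward models:

- **Beats / ECG.** Inter-beat intervals are inverse-Gaussian,
  `RR ~ IG(mu, lambda)` with `mu = 0.8 s` and shape `lambda = 1200`
  (SD about 21 ms, a typical resting short-window variability). The mean is
  modulated additively by the respiration signal at the beat time scaled by
  an RSA coupling gain (0.015 s/unit at low valence, 0.045 at high valence),
  so high-valence windows carry stronger cardio-respiratory coupling. The
  ECG waveform is a sum-of-Gaussians P-QRS-T template placed at beat times.
- **BVP.** A pulse kernel with a logistic upstroke centered exactly at
  `R + PAT` (default 0.25 s) and a fast exponential decay; the steepest
  ascent of a logistic is its center, and it stays there under zero-phase
  smoothing, so the planted pulse-arrival time is recoverable to one sample.
  Pulse amplitude defaults to 1.0 (the planted VP).
- **GSR.** Tonic drift plus Poisson skin-conductance responses
  (bi-exponential kernels, decay constant 3 s). Event rate grows with
  arousal (4/min at A1, 10/min at A4, linear in between) and the
  onset-to-peak rise time is longer at low valence (1.2 s vs 0.6 s),
  obtained by solving the kernel's rise constant for the requested peak time.
- **RESP.** A 0.25 Hz sinusoid, amplitude 1.5 units peak-to-trough.
- **Pupil.** Baseline 4.0 mm plus slow wander, band-limited low- and
  high-frequency noise (the 0.15-0.45 Hz RMS gain rises with arousal:
  0.04 mm at A1, 0.12 mm at A4), independent per-eye sensor noise, and
  Poisson blinks during which the diameter collapses below the 2 mm floor.
- **EEG.** 21 channels of independent per-band filtered noise. The parietal
  beta-band gain is scaled per window so the parietal beta/theta ratio
  realizes the quadrant's attention target (1.8, 1.3, 0.9, 0.55 for A1-LV,
  A1-HV, A4-LV, A4-HV), encoding the finding that attention decreases from
  low-arousal/low-valence toward high-arousal/high-valence states. Because
  each channel is independent, the common-average reference leaves the
  planted band structure intact.

Effect sizes are free parameters of the generator (the study that motivates
them reports only qualitative directions); the defaults above were chosen
once to be comfortably recoverable at the 45 s window length and are not
estimates of any real cohort. Everything is a pure function of the seed via
`numpy.random.SeedSequence` spawning. A `fast` rate set (ECG/BVP at 256 Hz
instead of 2048, EEG at 100 Hz instead of 300) exists for quick runs and is
recorded in the recording metadata; GSR/RESP/pupil rates are unchanged.

What the generator does **not** emulate: motion and electrode artifacts,
non-stationary baselines, ectopic beats, gaze-dependent pupil changes,
volume-conducted EEG sources, inter-subject effect-size heterogeneity
(subjects differ only by seed). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to real-world artifacts.

## Feature extraction

All extractors operate on one 45 s window at a time.

- **EEG (12).** Zero-phase FIR band-pass 1-45 Hz, common-average reference;
  Welch PSD (2 s Hamming, 50% overlap — at least four cycles of the 1 Hz
  edge per window while retaining averaging), averaged over channels within
  the frontal (Fp1, Fp2, Fz, F3, F4, F7, F8) and parietal (Pz, P3, P4, P7,
  P8) groups, assigned by 10-20 prefix and configurable. Per region: delta
  (1-3), theta (4-7), alpha (8-12), beta (16-38 Hz) powers normalized by the
  1-45 Hz total, plus attention (beta/theta) and engagement (beta/alpha)
  ratios computed from raw band integrals, where the normalizer cancels.
  Group PSD is the mean of per-channel PSDs, avoiding phase cancellation.
- **HRV (9).** ECG low-passed at 100 Hz and resampled to 250 Hz, R peaks by
  the Pan-Tompkins cascade with adaptive scale-free thresholds and
  search-back, detections refined to the local ECG maximum. The
  point-process model treats the IG mean of each interval as a linear
  autoregression (order 8) on previous intervals, fitted by maximum
  likelihood with an exponential forgetting factor 0.98; `mu_RR` is the
  time-averaged fitted mean and `sigma2 = mu^3/lambda`. Spectral indices
  integrate the AR transfer spectrum `sigma2 * dt / |A(f)|^2` over VLF
  (<0.04), LF (0.04-0.15) and HF (0.15-0.5 Hz), with the beat-domain
  frequency axis mapped to Hz by the mean interval. With order 0 and no
  forgetting the fit reduces to the closed-form IG MLE (tested), and the
  time-rescaling KS test on the fitted CDF transforms is the goodness-of-fit
  diagnostic. AR order, forgetting and the sigma2 definition are declared
  conventions exposed in the API.
- **BVP (2).** 25 Hz low-pass, 250 Hz resample; per RR interval the maximum
  is systolic, the minimum diastolic, and the onset is the steepest ascent
  between them (intervals without a rising segment, or inside the 0.25 s
  filter-edge guard, are skipped and counted). VP = mean systolic-diastolic
  difference; PAT = mean onset-minus-R delay.
- **GSR (17).** 2 Hz low-pass, 5 Hz resample; tonic = 4 s centered running
  median (window shrinking at the edges), phasic = residual. SCRs span an
  upward crossing of 0.01 uS to the next downward crossing of 0.0 uS with
  the peak at the span maximum; spans that never return below zero merge.
  The registry holds signal moments and absolute first/second differences
  (raw and within-window z-scored), tonic mean/slope, phasic mean/SD, SCR
  count/rate/amplitudes, mean rise time, and the mean derivative and maximum
  signed inter-extremum excursion of the 0.5-1 Hz band-passed signal. Only
  three of these are fixed by the source analysis; the rest are a frozen
  registry of standard electrodermal statistics so the width (17) and order
  are stable.
- **RESP + coupling (8).** Zero-phase equiripple (Parks-McClellan) 1 Hz
  low-pass; breaths are detected maxima (prominence-thresholded), amplitude
  the max-minus-preceding-min; `fRESP` = breaths / window duration. Coupling
  uses the beat-sampled (RR, RESP) series: a least-squares bivariate AR of
  order 6 provides the directional transfer gains — RSA (RESP to RR) and
  feedforward (RR to RESP) — evaluated as the ratio of the cross-lag
  polynomial to the own-lag polynomial of the target equation at the
  respiratory spectral peak within HF, where the drive actually has power;
  evaluated there, a planted additive coupling is recovered linearly
  (tested: doubling the coupling doubles the gain). Coherence and
  cross-spectral magnitude are Welch estimates on the beat series,
  band-averaged/integrated over LF and HF; Welch coherence of a noiseless
  linear relation is 1 by construction, which anchors the deterministic
  limit. This beat-sampled least-squares model is a desk-scale surrogate
  for a full bivariate point-process likelihood; its acceptance surface is
  the coupling-recovery properties, not millisecond-resolution dynamics.
- **Pupil (9).** Range rule (2-8 mm), jump rule (>0.375 mm within 20 ms,
  both endpoints invalidated), one-eye substitution, bilateral cubic-spline
  interpolation (gaps beyond 2 s flagged), binocular mean where both eyes
  are valid, then 5 Hz low-pass and decimation to 10 Hz. Welch on the
  linearly detrended trace with 1.875 s Hamming segments, 50% overlap. At
  10 Hz those segments give a raw grid of ~0.53 Hz, coarser than the
  sub-Hz bands, so the PSD is evaluated on a zero-padded (nfft=256) grid:
  band integrals and tone peak locations are then defined, at the cost of
  heavy spectral leakage between VLF/LF/HF — band values should be read as
  leakage-smoothed summaries. Registry: mean, SD, VLF/LF/HF powers
  (HF = 0.15-0.45 Hz), LFn/HFn, LF/HF, total.

Failed extractions never drop an observation: the affected cells are NaN and
the failure is appended to the row's `flags` column; imputation happens only
inside training folds of the classifier (median), preserving the leakage
guard.

## Square Method

For each feature pair and class, an axis-aligned rectangle is centered on
the class means with half-widths equal to the Student-t 95% CI of the mean
(t rather than normal because per-class n is at most a few dozen). For four
classes, each unordered intersection is scored twice — once against each
box's own area — giving 12 ordered ratios whose mean (x100) is the pair
score A. Pairs with A above the threshold are discarded; each feature's
weight W counts its surviving pairs; among features correlated above
|r| = 0.8 the lower-W one is discarded (equal W: seeded random choice,
processed in sorted name order so column order is irrelevant); surviving
features with W strictly above the mean W are selected, ranked by W. When
all survivors tie exactly (e.g. at the vacuous 100% threshold, where no pair
is discarded), the strict mean rule would select nothing although the ties
carry no ranking information; the implementation then keeps all surviving
uncorrelated features, matching the intended "all uncorrelated features"
reading of the 100% setting. Zero-area (degenerate) boxes score 1 against
boxes whose closure contains them and 0 otherwise, preserving the [0, 1]
range. The threshold sweep uses {100, 90, 70, 50, 30, 20, 10} plus LO, the
smallest integer percentage at which at least one feature survives.

## Classification benchmark

Seven families (KNN, decision tree, logistic regression, RBF SVM, LDA,
random forest, AdaBoost) run inside a pipeline of fold-local median
imputation and standardization. Cross-validation is 10-fold with folds
partitioning subjects — since every subject contributes one row per class
per phase, subject folds are automatically class-balanced; a fold missing a
class is redrawn with a fresh seed. Hyperparameter grids (not fixed by the
source analysis, configurable): KNN k in {1,3,5,7,9}; tree depth
{2,4,8,None}; LR C {0.01,0.1,1,10}; SVM C {0.1,1,10} x gamma
{scale,0.01,0.1}; RF {100,300} trees x depth {4,None}; AdaBoost
{50,100,200} estimators. The benchmark covers four conditions: all phases
together (with a held-out 7-subject test set; selection, imputation,
scaling and grid search see training rows only, and the best
threshold/model is retrained and scored once on the test side) and the
three per-phase 88-row subsets (cross-validation only).

## Problem sizes and numerical choices

The test suite and the acceptance script run the signal stages on reduced
cohorts (2-4 subjects, fast rates, shortened rest) and the feature-space
stages (selection, classification calibration) on full 264-row tables drawn
directly in feature space; design counts for the full 22-subject cohort are
verified on protocol timelines, which are cheap. Resampling uses rational
polyphase filtering with line padding (constant-baseline signals would
otherwise show large edge transients). Monte-Carlo box-overlap checks use
1e5 points (binomial SE < 0.2%). All randomness flows from explicit seeds;
identical seeds give byte-identical outputs.

## Known limitations

- Synthetic-only validation: classification accuracies on generated data
  say nothing about accuracies attainable on human recordings.
- The pupil spectral bands are leakage-smoothed (see above).
- The bivariate coupling model is beat-sampled and stationary per window;
  time-varying gain trajectories are out of scope.
- SCR rise times measured after median-filter decomposition are compressed
  relative to the planted kernel times (the tonic median absorbs part of
  slow events); orderings are preserved and tested, absolute values are not.
- The EEG artifact pipeline of real recordings (ICA component rejection,
  channel interpolation) is replaced by band-pass + common-average
  referencing, which is sufficient for artifact-free synthetic data.
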