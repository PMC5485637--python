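# Methods

## The task being modelled

Adolescent participants freely view naturalistic peer scenes for 5 s
(binocular recording at 300 Hz), then see the scene with a positive or
negative interpretation statement for 3 s and rate the statement's
likelihood on a 0–100 visual analogue scale. Each of 72 scenes appears once
per participant (6 blocks of 12), in either the self or the other
perspective condition, counterbalanced across participants. The analysis
asks whether dwell time on peer faces, social anxiety (SAS-A) and age
predict the interpretation ratings.

## Geometry

Pixel ↔ degree conversion uses the linear small-angle convention
`deg_per_px = (2.54 / ppi) / distance_cm · 180/π`; with the default 94 ppi
panel at 57 cm this gives 0.02716 °/px, so the 1200 px scene spans 32.6°.
The arctangent form differs by < 1 % at these distances; the linear form is
the one consistent with the spans quoted for this display geometry. All
thresholds specified in degrees (noise, dispersion, velocity, calibration
radius) are converted through this one constant, and the geometry is fully
configurable.

## Cleaning chain

* **Validity** (per sample, both eyes): tracker found the eye, gaze inside
  the screen, pupil positive and within a physiological band. The band
  defaults to 1.5–9.0 mm; only "positive and physiological" is prescribed by
  the protocol, the numbers are this package's defaults and configurable.
* **Filters**: gaze is smoothed with a Savitzky–Golay filter (order 2,
  window 7 samples ≈ 23 ms); edges use scipy's truncated-window polynomial
  fit. Pupil uses a 3-sample running median whose half-window edges pass
  through unchanged. (A 3-sample window at 300 Hz spans 10 ms; the window is
  specified in samples, which is what the implementation follows.)
* **Blinks**: samples where the absolute first difference of pupil diameter
  exceeds 0.1 mm *in both eyes* form blink sections; the threshold is
  interpreted per sample at the nominal rate ("instantaneous" rate of
  change) and is configurable. Section samples are invalidated for gaze and
  pupil. Around a real blink this flags the collapse and recovery ramps;
  the occluded plateau between them is already invalid through the tracker
  flag and the physiological pupil bound, so the combined mask covers the
  whole artifact.
* **Repair**: invalid gaze is replaced by the last valid value (leading
  invalids take the first valid value); invalid pupil is linearly
  interpolated between flanking valid samples. Repair never alters valid
  samples; QC always sees the *pre-repair* mask.
* **Baseline**: pupil is baseline-corrected by subtracting the mean of the
  200 ms before scene onset, per eye.
* **Drift**: per trial, the offset between the fixation-cross position and
  the median valid analysis-eye gaze during the cross window is applied to
  all gaze samples only if its Euclidean magnitude is below 150 px
  (a per-axis variant is available). The median is used as the cross-window
  summary because it is robust to residual saccades. If the cross window
  has no valid samples the trial is flagged `drift_uncorrectable`; an
  offset ≥ 150 px leaves the trial in the analysis uncorrected.
* **Participant vertical correction**: when the participant-level median of
  the per-trial vertical cross offsets exceeds 30 px (a package default —
  the original procedure applied this ad hoc to a few participants), that
  constant is removed from all y samples before per-trial drift correction.
  The operation is idempotent.

## Trial and participant QC

Three rules on the pre-repair validity mask, with strict inequalities
exactly as worded: (i) an invalid run > 1000 ms anywhere from fixation
onset to trial end, (ii) an invalid run > 1000 ms between fixation onset
and scene offset, (iii) > 40 % invalid samples between fixation onset and
scene offset. A run of exactly 1000 ms (300 samples) is retained; a 1 µs
float guard keeps the boundary exact under sample-period rounding.
Participants need ≥ 30 valid trials in each *perspective* condition
(self/other). Perspective is the only factor with 36 trials per cell;
crossing with valence (18 per cell) would make a 30-trial criterion
unsatisfiable, so "per condition" is read as perspective and the threshold
is configurable. Calibration QC checks ≥ 12 samples within 1° at each of 9
points (20/50/80 % of both spans).

## Fixation detection and AOI dwell time

Candidates are samples with gaze speed < 75 °/s (central difference over
two samples of the smoothed left-eye gaze, one-sided at slice endpoints).
Contiguous candidate runs are scanned left to right with a running
centroid; a fixation closes at the previous sample whenever the incoming
sample would lie > 2° from the updated centroid (greedy centroid-update
splitting — the thresholds are prescribed, the grouping algorithm is this
package's choice). Groups shorter than 75 ms are discarded; no post-hoc
merging across gaps is performed. Dwell time is the summed duration of
fixations whose *centroid* falls in any peer-face rectangle of the scene,
clipped to the 5 s window (per-sample assignment is available behind a
config switch).

## Questionnaires

SAS-A: 22 items on 1–5; the 18 scored statements are summed (range 18–90),
with the 50–54 clinical cut-off band annotated. The filler positions
(2, 8, 15, 22) are a package convention — scoring depends only on which 18
items are summed. PDS: four development items (1–4) plus menarche
(yes = 4 / no = 1) averaged over 5.

## Statistical model

Ratings are modelled on their raw 0–100 scale with crossed random
intercepts for subject and scene. Factors are effect-coded −0.5/+0.5
(other/self, negative/positive) and continuous predictors (AOI fixation
time; anxiety or age) are z-scored across retained trials; the original
report does not state its coding, so printed coefficient magnitudes are
not directly comparable — the machinery, not the numbers, is what this
package reproduces.

Fitting is by **maximum likelihood**, not REML, because AICs are compared
across fixed-effect structures (a deliberate deviation from the lme4
default). The fitter profiles β and σ_e² out of the deviance and optimises
the two variance ratios (log λ_s, log λ_c) by Nelder–Mead, with all
quadratic forms reduced through the Woodbury identity to dense algebra on
the q = S + C random-effect cross-products; candidate scans warm-start at
the global model's optimum. Tests cross-check log-likelihoods, estimates
and standard errors against a generic variance-component ML fit
(statsmodels MixedLM) and against OLS in the σ→0 limit. Non-converged
candidates are dropped from the weight normalisation with a warning.

The candidate set contains every marginality-closed subset of the 15-term
global model (167 candidates including the intercept-only model): "all
combinations" is constrained so that an interaction never appears without
its lower-order terms. AIC = −2 logLik + 2k with k = p fixed coefficients
(incl. intercept) + 2 variance components + residual variance. Averaging
is *full* (zero-substituting) by default — the default reporting style of
the information-theoretic approach — with conditional averaging behind a
flag; unconditional SEs follow Burnham & Anderson, CIs use the normal
quantile 1.96 without a df correction, and p-values come from the normal
approximation z = θ̄/SĒ (the original's p-value method is unstated).

Full averaging is deliberately conservative for weakly supported terms:
shrinkage toward zero plus between-model SE inflation pushes the null
false-positive rate well below the nominal 5 % (the test suite measures
~0.5–2 %), which is treated as an upper-bound property, not a calibration
target.

## Synthetic-data generator

The generator defines the study conditions for every test:

* **Design**: 72 scenes × 6 blocks × 12 trials, perspective and valence
  counterbalanced across participants, random order per participant.
* **Trial timing**: fixation cross jittered 1–2 s, scene 5 s, scene +
  statement 3 s, rating 0.5–2.5 s later, inter-trial interval 5–6 s;
  sampled continuously at 300 Hz per participant.
* **Gaze**: fixation targets ≥ 4° apart (random scene points or peer
  AOIs), joined by linear saccades at ~250 °/s (duration 4 ms/deg, clipped
  to 20–60 ms) — saccade shape only needs to be detectable as non-fixation.
  Noise is an isotropic AR(1) Gaussian process specified in degrees
  (marginal sd 0.3°, lag-1 correlation 0.99): white noise of that marginal
  sd at 300 Hz would imply ~60 °/s RMS velocity noise, which no video
  tracker exhibits, while AR(1) with ρ = 0.99 matches the ~0.05° RMS
  sample-to-sample precision published for 300 Hz trackers. Per-trial
  constant drift offsets (sd 20 px) and an optional participant vertical
  bias exercise the corrections.
* **Blinks**: per-trial probability 0.25 (duration 100–300 ms); both pupil
  channels ramp to a floor at ≥ 0.3 mm/sample and the tracker flag goes
  invalid, so both detection pathways are exercised. Ground-truth events
  are carved so the per-trial event list stays non-overlapping; fixation
  fragments under 75 ms (the detectable minimum) are dropped from the
  truth.
* **Questionnaires**: SAS-A totals around the community norms for
  adolescent females (mean ≈ 47, sd ≈ 10.6), PDS in the mid-to-late
  pubertal range, ages uniform on [14, 19.75].
* **Ratings**: drawn from the crossed random-intercepts model with
  predictors coded exactly as fitted, truncated (not resampled) to
  [0, 100] as a bounded VAS. The default recovery truth has intercept 50,
  anxiety 2.9, perspective:valence 4.2, valence:fixation −4.8,
  valence:anxiety −4.5, with σ_subject = 6, σ_scene = 4, σ_resid = 20 —
  magnitudes and uncertainty chosen to match the scale of published
  community-sample results of this design (e.g. an anxiety SE near 0.9
  at ~50 subjects), with the residual kept moderate so truncation stays
  mild. Scene-level gesture coding is not modelled; valence enters as a
  per-scene design factor only.

What the generator does **not** emulate: realistic oculomotor dynamics
(main-sequence velocity profiles, microsaccades, smooth pursuit),
photographic scene content, vendor-specific data quirks, or
heteroscedastic/heavy-tailed rating noise. Passing tests therefore show
that the pipeline recovers known structure under idealised but
plausibly-scaled conditions; they do not certify performance on any
particular tracker's real output.

## Problem sizes and numerical choices

The parameter-recovery experiments use 50 subjects × 72 scenes per
replicate, with 40 coverage replicates and 40 null replicates in the
acceptance suite (the acceptance script uses 12 + 12); detector recovery
uses 200 simulated trials; end-to-end determinism uses 2 participants.
Nelder–Mead tolerances are xatol 1e-4 / fatol 5e-8 on the profiled
deviance; the residual sum of squares is floored at 1e-12 to keep the
degenerate zero-variance case finite; Akaike weights are computed after
subtracting the minimum AIC. Ties in the dispersion split are broken by
the strict `>` comparison (the incoming sample stays in the group at
exactly 2°). Degenerate inputs (all-invalid streams, empty QC windows,
< 2 subjects or scenes, constant predictors) raise ValueErrors rather than
proceeding.

## Known limitations

* Real gaze recordings violate the generator's independence assumptions;
  detector boundary accuracy (±10 ms) degrades with non-stationary noise.
* The pupil analysis ends at baseline correction; no event-locked pupil
  statistics are computed.
* Coefficient magnitudes are coding-dependent; comparisons with published
  tables of this design are qualitative (sign and significance pattern),
  not numeric.
* The averaging CIs are normal-approximation intervals; for very small
  subject counts a df-adjusted interval would be wider.
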