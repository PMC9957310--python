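# Methods

`ergofield` implements a field-ergonomics measurement pipeline for full-shift
occupational studies: directly measured physical workload (heart rate, surface
EMG) is reduced to two physiological outcome metrics — percent heart-rate
reserve and the EMG median-power-frequency fatigue slope — and related to
subjective effort ratings through a battery of correlation, regression and
rank tests. Because field datasets of this kind are small, noisy and hard to
re-collect, the package ships a synthetic-cohort generator with known ground
truth so that every stage of the pipeline can be validated end to end.

## Study design the pipeline assumes

A cohort of male orchard workers, split evenly over three harvesting methods
(**Ground**, **Ladder**, **Platform**), works one shift (default 7:30–15:00)
with a single mid-morning break. Effort surveys are administered at four
timepoints:

- **T0** — pre-shift, alongside a 15-min quiet-sitting heart-rate measurement;
- **T1** — end of the first work bout (the heart-rate window is the last
  10 min of work *before* the break, since the worker is idle while being
  surveyed);
- **T2** — immediately after the rest break (10-min window);
- **T3** — end of shift (last 10 min of work).

The break duration is configurable; both a 30-min-rest layout and a 90-min
(9:00–10:30) layout ship as presets because field protocols differ on this
point. All clock arithmetic uses integer seconds-of-day and half-open
`[start, end)` windows so boundary samples are never counted twice.

## Direct measures

### Percent heart-rate reserve (%HRR)

Heart rate is recorded at 1 Hz. Single-sample artifacts (telemetry dropouts,
strap motion) are removed with a **5-point moving median**; at the recording
edges the window shrinks rather than padding, so no data are invented. Period
means are taken over the survey-aligned windows with a coverage fraction
(samples present / expected at 1 Hz); windows below a configurable minimum
coverage (default 50%) are flagged. The metabolic-load metric is

    HRmax  = 220 − age
    HRrest = HRsit − 10
    %HRR   = (HRwork − HRrest) / (HRmax − HRrest)

where `HRsit` is the T0 sitting mean. The −10 bpm adjustment approximates a
recumbent resting rate from a seated field measurement. %HRR values outside
[0, 1] are physiologically possible under this approximation and are
**flagged, not clipped**; negative values are excluded (with a count) from
the square-root transform. The square-root transform is applied for
normality before parametric modelling and Shapiro–Wilk statistics are
reported both before and after, so the choice is auditable. Which scale
(`hrr` or `hrr_sqrt`, default the latter) feeds the association battery is a
config switch.

### EMG median-power-frequency fatigue slope

Bilateral trapezius surface EMG is sampled at 1000 Hz. Processing per
recording:

1. **Bandpass 20–450 Hz**, 4th-order Butterworth applied forward–backward
   (zero phase; the doubled effective order gives > 40 dB attenuation one
   octave beyond the cutoffs).
2. **10-min windows** from shift start. Per window: rectified-amplitude
   percentiles (10/50/90), mean power frequency (MNF), median power
   frequency (MDF), and total in-band power, from a Welch estimate with 1-s
   Hann segments at 50% overlap (1-Hz resolution — a stable density at the
   10-min scale). The MDF is the half-power crossing of the trapezoid
   cumulative of the density, linearly interpolated, so a flat spectrum on
   [20, 450] Hz yields the band midpoint 235 Hz. Windows are stamped with
   both clock minutes (`t_mid`) and cumulative **work** minutes (`t_work`),
   and flagged `in_break` when they mostly overlap the break.
3. **PCA artifact screen.** Field EMG suffers electrode lift-off, cable
   motion and amplifier saturation. Per subject-side, the six window
   features are z-scored, projected on the principal components covering
   90% of variance, and a robust squared distance (median center, MAD scale
   per component) is referred to a chi-square quantile (default 0.999).
   Flagged windows are excluded downstream. The quantile and variance
   fraction are config parameters; on clean synthetic data the screen flags
   well under 1% of windows while catching essentially all injected
   clipping/drift contamination.
4. **Fatigue slope.** Per subject-side, OLS of MDF on time over
   non-break, non-anomalous windows (`MPF = b0 + b_time·time`); fewer than
   3 usable windows yields an explicit missing record. A spectral
   compression (negative `b_time`, Hz/min) is the localized-fatigue signal.
   The regressor defaults to cumulative work minutes — a fatigue process
   that pauses during rest — with clock time available as a switch, because
   printed slopes in the field literature are often ambiguous about this
   convention and the two differ once a break interrupts the shift.
   "MPF" is taken as the **median** power frequency by default (config
   switch to mean); both are stored for every window regardless.
5. **Pooled model.** `mdf ~ time + side + subject` (fixed effects) removes
   the level differences between sides and subjects — raw pooled MDF is
   bimodal because the non-dominant side sits at a different spectral level
   — and reports the pooled within-recording fatigue rate with its p-value.

## Subjective measures

Borg RPE (6–20, whole body), Omni RPE (0–10, whole body, pictorial) and Borg
CR10 (0–10, one rating per shoulder; halves allowed) are validated against
their ranges, sites and duplicate keys, with per-row rejection reasons.
Analyses use **changes from the T0 baseline** (T1–T3 deltas), which removes
idiosyncratic anchoring of the scales; the CR10 end-of-shift change
(T3 − T0 per shoulder) is additionally labelled dominant/non-dominant via
the roster. A missing baseline produces a missing-data record, never a zero.
The Omni range 0–10 is the standard format and is overridable in config.

## Association battery

With %HRR per subject-period joined to the same-period RPE deltas (the
period label is the join key; T1/T3 HR windows cover the work bout right
before the survey):

- unadjusted Pearson correlations per direct/subjective pair;
- OLS adjusted for the known confounders (work period, harvesting method for
  overall effort; harvesting method and side dominance for local
  discomfort), treatment coding, alphabetically first reference level;
- the same associations stratified by harvesting method (adjusting period)
  and by period (pooling methods); strata below n = 3 are reported missing;
- Spearman rank correlation between the Borg and Omni deltas;
- two-way ANOVA (group, period; sequential sums of squares) with Tukey HSD
  on `hrr_sqrt`;
- Kruskal–Wallis (tie-corrected) with Dunn pairwise rank-sum z-tests on the
  rating deltas, unadjusted p by default (a Holm option exists) — matching
  the common field-analysis convention of reporting raw Dunn p-values.

All confidence intervals are 95%. Correlation CIs use the Fisher transform.
Dunn's test is implemented in-package (mean-rank difference over the
tie-corrected variance) and is cross-checked against a brute-force mid-rank
oracle in the tests.

## Synthetic-data generator

The generator's defaults are the study conditions: 3 groups × 8 workers,
ages uniform on 18–47, the 7:30–15:00 shift, 1-Hz heart rate, 1000-Hz EMG,
all four survey instruments.

- **Latent exertion** per subject-period in [0, 1] with group-level means
  (Ladder > Ground > Platform; light right after the break) and per-subject
  jitter (sd 0.05). T0 is 0.
- **Heart rate** = sitting baseline (N(75, 5) bpm) plus
  `hr_gain · exertion` (default 60 bpm per unit) during work, Gaussian
  noise (sd 3 bpm), and isolated spike artifacts at rate 1e-3/sample to
  exercise the median filter.
- **EMG** is built second by second: each 1-s block is Gaussian noise
  spectrally shaped (in the frequency domain) to the analytic
  squared-magnitude response of a 4th-order Butterworth bandpass (default
  width 80 Hz) whose center is `intercept + slope · work-minutes`, frozen
  during the break. This is spectrally identical to filtering white noise
  through the same time-varying Butterworth, vectorizes cleanly, and the
  block length (1 s) is far below the 10-min analysis window. The
  per-window MDF of the noiseless generator is available in closed form
  (`expected_mdf`, numeric integration of the analytic response) and is the
  oracle for the spectral tests; its offset from the programmed center
  drifts by about 1% of the center change across the band, which bounds the
  (negligible) bias of slope recovery. The non-dominant side gets a +8 Hz
  intercept offset, reproducing the bimodal pooled-MDF distribution of
  bilateral recordings. Contaminated windows can be injected (hard clipping
  at 0.6 × RMS; a 20 × RMS 15-Hz drift component) for screen testing.
- **Ratings** are drawn through a Gaussian copula on ranks: latent exertion
  is converted to normal scores via mid-ranks and each rating's latent is
  `ρ_g·z + sqrt(1−ρ_g²)·ε`, with `ρ_g = 2·sin(π·ρ_s/6)` inverting the
  bivariate-normal Spearman relation so the population rank correlation
  equals the programmed `rating_rank_correlation` (default 0.6).
  Discretizing to scale steps attenuates the realized correlation by a few
  percent; `calibrate_copula_rho` quantifies this by simulation. Delta
  coding attenuates further (the baseline contributes independent noise),
  which is why between-scale delta correlations are reported as monotone
  recoveries rather than point targets.

What the generator does **not** emulate: heart-rate variability and
thermoregulatory drift, motion artifacts beyond isolated spikes, realistic
EMG amplitude–force coupling, non-stationary within-window spectra, and
informative missingness. Passing recovery tests therefore demonstrates that
the estimators are correct under the stated model, not that field data meet
that model.

## Validation batteries and their sizing

Sizes are chosen for a single CPU while keeping Monte-Carlo error well below
each tolerance:

- **Slope recovery**: 100 replicates per programmed slope in
  {0, −0.005, −0.01, −0.05} Hz/min on a 100-min shift (9 work windows).
  The mean recovered slope must lie within max(10% of |truth|, 2 × MC SE);
  measured errors are an order of magnitude inside that band.
- **Anomaly screen**: 6 clean + 5 contaminated 4-h recordings
  (24 windows each, 5 injected per contaminated recording); detection vs
  false-positive rates at the default threshold.
- **Type-I calibration**: 200 replicate 24-worker cohorts with
  `rating_rank_correlation = 0`, each run through the real %HRR pipeline.
  Each test (Pearson, Spearman, Kruskal–Wallis, adjusted-regression
  predictor) is evaluated at the end-of-shift period — one independent row
  per subject — because the generator's shared T0 baseline and shared
  sitting HR correlate rows *across* periods within a subject, so a pooled-
  period calibration would be testing a clustering artifact, not the tests.
- **Rating-correlation sweep**: mean pooled Spearman between Borg and Omni
  deltas over programmed ρ ∈ {0, 0.3, 0.6, 0.9} (400 replicates in the
  test suite), asserted monotone increasing; and the CR10-change vs
  `b_time` correlation, which the generator leaves decoupled, asserted
  within 2 SE of zero.
- **Recovery report** (`ergofield recover`): per-dataset mean absolute
  errors of HR work means (band 2 bpm), %HRR (0.05), `b_time`
  (0.02 Hz/min), and the realized rating rank correlation
  (2/sqrt(n−3) Fisher band at the realized number of pairs).

## Numerical conventions and degenerate inputs

Empty HR windows raise rather than returning 0; zero-power EMG windows are
flagged anomalous with NaN spectral features; constant feature columns are
dropped from the PCA screen; a constant score direction gets infinite MAD
scale (no evidence); slope fits with < 3 windows, strata with < 3 cases and
subjects lacking a survey baseline all produce explicit missing records.
Rank-deficient regressions surface through the underlying least-squares
machinery rather than being silently repaired. Every generator stream is
keyed on (seed, stage, subject, side) so runs are bit-reproducible; the
pipeline manifest records per-stage counts and SHA-256 checksums of every
output, and two runs with the same seed and config are byte-identical.

## Known limitations

- The anomaly screen reconstructs a described feature-set approach
  (amplitude percentiles + spectral summaries + PCA distance); it is a
  faithful operating-point match, not a bit-level port of any particular
  field algorithm.
- Fixed-effects adjustment is used throughout; repeated-measures /
  mixed-model inference is out of scope, and pooled-period association
  p-values should be read accordingly.
- The generator's exertion→rating copula is stationary across timepoints;
  real raters drift and anchor.
- `%HRR` depends on the `220 − age` maximum-rate formula and the
  sitting-minus-10 resting approximation; both are conventions, and errors
  in them propagate directly into the metric.
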