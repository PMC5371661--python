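# Methods

`socialgaze` implements the analysis chain of a free-viewing eye-tracking
study comparing bottom-up saliency with social attention: participants view
color photographs of complex scenes (half containing people) for 10 s each
while gaze is recorded at 1000 Hz, and the analyses ask how well a
low-level saliency map predicts where people actually look, how strongly
heads and bodies are prioritized relative to their size and their physical
saliency, how these influences evolve over the first five fixations, and
how saliency, social content and central bias jointly predict fixation
density in a scene-patch mixed-model analysis.

## Viewing geometry

All angular quantities are tied to pixels through one geometry: a
30.6 × 23.0 cm stimulus at 57.5 − 5 = 52.5 cm viewing distance, rendered at
1200 × 900 px, subtending 32.5° × 24.7°. Visual angle uses the exact
tangent form `2·atan(extent/2d)`; degree↔pixel conversion is linear in the
full-screen scale (≈36.9 px/° horizontally). Two constants are
deliberately *not* recomputed from the geometry but fixed at their
conventional values: the density-map smoothing kernel σ = 36 px ("1°") and
the foveal analysis window of 72 px diameter ("2°"). Both follow the
procedure as printed; the ≈2.5% difference from 1200/32.5 is irrelevant
downstream and configurable.

## Event detection

Samples are classified by velocity/acceleration thresholds: a sample is a
saccade sample when speed > 30°/s or |acceleration| > 8000°/s², estimated
by central differences over a 5-sample window (the original proprietary
parser's filter is unpublished; the window length is configurable).
Blinks are maximal runs of missing pupil data and dominate classification;
a trial is valid only if blink time during scene presentation stays under
2 s. Runs between saccades and blinks of at least 40 ms become fixations
at the mean position of their samples (the 40-ms floor suppresses
jitter-induced micro-events; the threshold papers leave it open).
Fixations must start after scene onset; those straddling scene offset are
truncated there.

Drift correction uses the 300 ms before scene onset, when the observer
fixates a central cross: the mean position of fixation-classified samples
in that window is the trial's baseline. Per participant and axis, a
recursive outlier filter runs over the baseline distribution: the current
minimum and maximum are removed, each is tested against mean ± 3 SD
(n − 1 denominator) of the remainder, any extreme strictly beyond the
bound is discarded permanently, and the procedure repeats until neither
extreme is removed. Flagged or missing baselines are replaced by the mean
of the valid ones (and such trials are excluded from the early-fixation
analyses, where the starting position matters). Every fixation is then
shifted by `cross − baseline`; the sign convention — raw plus offset — is
our choice, verified by round-trip recovery of injected offsets. The
baseline averages fixation-period *samples*, not fixation centroids;
either reading is compatible with the source description.

## Density maps and comparison metrics

Per participant × scene, fixation durations (ms) are deposited at rounded
fixation pixels, convolved with an isotropic Gaussian (σ = 36 px,
truncated at 4σ, zero padding), and min-max normalized to [0, 1]. The
implementation splats one truncated separable kernel patch per fixation,
which is algebraically identical to convolving the impulse accumulator
(tested against `scipy.ndimage.gaussian_filter`) and ~two orders of
magnitude faster at ~30 fixations per trial.

For the saliency–density comparison both maps are ε-regularized
(ε = 10⁻¹², stable over 10⁻¹⁵…10⁻⁹) and rescaled to sum to 1.
`D_KL = Σ F·log(F/S)` is computed with F the fixation density and S the
saliency map — the "how badly does saliency predict fixations" direction;
the direction and log base (natural by default) are configuration options
because the convention is not universal. AUC treats saliency values as
classifier scores for the binarization of the density map at its own mean,
computed as the rank-based Mann–Whitney area with midranks for ties —
equivalent to all-pairs concordance counting (tested against that oracle).
Pearson r correlates the two sum-normalized maps over all pixels. Trial
metrics are averaged per participant separately for social and non-social
scenes and compared by two-tailed paired t-tests.

## ROIs, time course, patches

Social scenes carry hand-drawn (here: generated) head and body masks, body
excluding head. Among the remaining pixels, saliency values at or below
the 8th decile (80th percentile, linear interpolation; ties go to the
lower region) form the lower-saliency ROI and the rest the
higher-saliency ROI, yielding a full partition. Relative ROI saliency is
ROI mean over scene mean. Gaze allocation per ROI is the ROI's share of
density mass divided by the ROI's share of scene area, so uniform gaze
scores exactly 1 everywhere; the area unit is the dimensionless scene
fraction (any constant cancels between ROIs).

The time-course analysis scores each of the first five fixations by the
mean saliency in a 2°-diameter circular window around it over the scene
mean, and (for social scenes) by the ROI label at its pixel; off-image
fixations have no label and are excluded from both numerator and
denominator of the hit frequencies. Hit frequencies are normalized by the
mean area fraction of the ROI across exactly the scenes represented in the
cell. A pooled "6+" bin summarizes the trial tail for plotting.

The patch analysis overlays a 12 × 9 grid of 100 × 100 px patches. Per
patch: relative fixation density, relative saliency, relative head and
body coverage (each normalized to per-scene mean 1; scenes with no head
pixels get 0 with a warning) and the Euclidean distance of the patch
center to the scene center (27 distinct values on this grid; minimum
50 px). The four predictors are z-standardized over the pooled table;
interaction terms are products of standardized mains and are not
re-standardized (the original treatment is unreported; the choice is
recorded in the scaling report).

## Mixed models

The model ladder regresses relative fixation density on growing
fixed-effect sets (center distance; saliency; head; body; their
combinations; saliency × head and saliency × body interactions) with
crossed random intercepts for participant and scene. The solver profiles
the deviance in the lme4 manner: with Z the two-factor indicator matrix
and Λ(θ) the diagonal relative-SD scaling, the fixed effects and residual
variance are profiled out and only θ = (σ_participant, σ_scene)/σ_residual
is optimized (L-BFGS-B, three starts, 10⁻⁸ tolerance on the profiled
deviance). All linear algebra runs on precomputed cross-products, so one
fit on 264k rows takes a fraction of a second, and the estimates reproduce
lme4's coefficients, standard errors, variance components, REML/ML
log-likelihoods and AIC to printed precision on reference data.
Coefficients and their tests come from the REML fit; likelihood-ratio
tests (χ² = 2·Δlog L, df = Δk) and AIC (k = fixed effects + 2 variance
components + residual) use the ML fit. Fixed-effect p-values use the Wald
statistic against the normal reference: with n ≈ 2.6 × 10⁵ the difference
from a finite-df approximation (Satterthwaite) is far below printed
precision. R² is reported as the squared correlation between observed
values and conditional (BLUP-including) predictions. Decile summaries bin
patches by each predictor's deciles (plus a zero-coverage bin for head and
body; center-distance bins are uneven because only 27 distinct values
exist).

## Repeated-measures statistics

One- and two-way within-subject ANOVAs use the univariate sums-of-squares
decomposition with participant × factor interactions as error strata,
which yields the conventional df (e.g. F[4,120] for 31 participants × 5
ranks). Sphericity is handled by Huynh–Feldt's ε derived from the
Greenhouse–Geisser estimate on the effect's orthonormal contrast space,
`ε_HF = (n·m·ε_GG − 2)/(m·(n − 1 − m·ε_GG))` with m the numerator df,
clamped to [1/m, 1]; ε is applied whenever m > 1 and equals 1 exactly for
two-level factors. Effect sizes are partial η² = SS_eff/(SS_eff + SS_err)
and, for paired contrasts, Cohen's d for paired data in the d_z form
(mean difference / SD of differences; the pooled-SD two-sample form is
available via a flag since the printed formulation is ambiguous across its
cited sources). Post hoc pairwise paired t-tests use a Bonferroni
threshold α/m. Validity is checked behaviorally: under a
sphericity-violating AR(1)-with-heteroscedasticity null, the HF-corrected
type-I error stays in [0.03, 0.07] over 1000 simulations.

## Synthetic data generator

No gaze recordings or stimuli are deposited, so the package ships a
generator whose defaults encode the study conditions: 31 participants ×
160 trials (80 social / 80 non-social), 10-s viewing after a central
cross, ~31 fixations per trial (duration ~ truncated Normal(277, 48) ms,
min 40 ms), saccade amplitudes ~ truncated Normal(4.7°, 1.3°), occasional
blinks (Poisson, 1.5 per trial, ~150 ms), a constant per-trial tracker
drift (SD 6 px) and temporally correlated fixation jitter (SD 0.05°,
smoothed over ~8 ms — white per-millisecond jitter would alias into
>15°/s velocity noise no real tracker shows).

Scenes are constructed, not photographed: a right-skewed two-scale noise
background, six plateau-like high-saliency distractor objects with
center-biased eccentricity (photographer composition bias), and — in
social scenes — head and body ellipses covering 2.15% and 8.95% of the
scene at ~9.6° from center, whose saliency is set to ~1.2× the scene mean.
The saliency map is constructed directly rather than computed from the
rendered image, so the curated stimulus property the analyses rely on
(higher-saliency areas > heads ≈ bodies > lower-saliency areas) holds by
design; non-social scenes receive matched mid-saliency object regions so
the two categories have statistically comparable saliency distributions.
The bundled center-surround reference saliency model is validated
separately on toy images and available for user-supplied photographs.

The scanpath model draws each saccade target from a mixture of components
{head, body, saliency-driven, center-biased noise} with weights
(0.35, 0.18, 0.27, 0.20). Two rank schedules shape the time course:
the saliency-driven component samples locations proportional to
saliency^γ with γ = (3.0, 2.0, 1.4, 1.0, 0.8) over fixations 1–5 and 1.6
for the pooled tail — sharply peaked early (bottom-up capture), flatter
across the early exploration, and object-anchored in the steady state —
and the head weight is multiplied by 3.5 for ranks 1–2, the window in
which a centrally starting observer can first reach a 9.6°-distant head
given ~4.7° saccades. Social targets are pursued across saccades
(commitment) while unreachable saliency/noise draws are single exploratory
steps; gaze resting on a head damps the head weight (×0.15) so dwell does
not dominate. These mechanisms — not per-rank output targets — generate
the qualitative pattern end-to-end: greater saliency–fixation divergence
for social scenes, the head > body > higher > lower ROI ordering, the
declining saliency-at-fixation profile, and the head-arrival peak at the
second fixation. The boost window, damping, γ schedule and blob shape are
calibrated generator mechanisms; they are modeling conveniences that
reproduce the reported phenomena, not claims about the original data.
A separate harness (`generate_patch_data`) simulates the patch design
with known fixed effects and variance components for parameter-recovery
testing; its response is built from the standardized predictors exactly as
the fitted models see them.

What the generator does not emulate: photographic image content (the
rendered images are visual sugar over the constructed saliency maps),
smooth pursuit, microsaccades, pupil dynamics beyond a validity flag,
saccadic undershoot dynamics, and any participant-level covariates.
Passing tests therefore demonstrate that the pipeline measures what it
claims on data with known truth — not that the scientific conclusions
transfer to any particular real dataset.

## Problem sizes and numerical choices

The default test suite runs the full 31 × 160 cohort once for the
end-to-end checks (~6 min), five replicates of the 264k-row
parameter-recovery study, and 1000-replicate nulls for the ANOVA
calibration. Degenerate inputs are defined rather than left to chance:
constant saliency maps give AUC 0.5 and r 0 (flagged); zero-fixation
trials give flagged all-zero maps; empty ROIs score `None`; a singular
random-effect variance is reported with a warning but the fit retained.
Ties at the saliency decile go to the lower region; fixation positions are
rounded to the nearest pixel before deposition; off-image fixations are
dropped from maps and label-based analyses with warnings.

## Known limitations

- The event detector uses fixed thresholds and a simple central-difference
  velocity estimate; it is validated against the generator's ground truth,
  not against a proprietary parser's output on real recordings.
- p-values for mixed-model fixed effects use the normal reference; at
  small n (hundreds of rows) a Satterthwaite approximation would differ.
- The reference saliency model is a didactic center-surround
  implementation, not a benchmark-competitive model; analyses accept any
  externally computed map.
- Baseline averaging uses fixation samples rather than fixation centroids;
  with stable fixations the two differ negligibly, but they are not
  identical.
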