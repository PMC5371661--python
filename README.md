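# socialgaze

Analysis of eye movements during free viewing of complex scenes, built for
studies that pit **bottom-up physical saliency** against **social
attention**. The package takes raw 1000-Hz gaze samples (or fixation
lists) and produces the statistics such a study reports:

- **Saliency-based prediction of fixations.** Per trial, a
  duration-weighted, Gaussian-smoothed fixation density map F is compared
  with the scene's saliency map S after both are rescaled to sum to 1:
  the Kullback–Leibler divergence D_KL = Σ F·log(F/S), the ROC area (AUC)
  of saliency scores predicting the above-mean-density binarization of F,
  and the pixelwise Pearson r. Per-participant means for social vs.
  non-social scenes feed two-tailed paired t-tests with Cohen's d for
  paired data.
- **Region-of-interest analysis.** Social scenes are partitioned into
  heads, bodies, and lower-/higher-saliency areas (split at the 8th
  saliency decile of the non-social pixels). Each ROI is scored by
  relative saliency (ROI mean / scene mean) and by area-normalized gaze
  allocation (share of density mass / share of scene area), compared by
  one-way repeated-measures ANOVAs with Huynh–Feldt correction, partial
  η², and Bonferroni post hocs.
- **Early-fixation time course.** Relative saliency in a 2°-diameter
  foveal window at each of the first five fixated locations, and
  area-normalized ROI hit frequencies per fixation rank, analyzed with
  5 × 2 and 5 × 4 within-subject ANOVAs.
- **Scene-patch linear mixed models.** Each scene is divided into a
  12 × 9 grid of 100 × 100 px patches; relative fixation density per patch
  is regressed on standardized center distance, saliency, head and body
  coverage (and saliency × social interactions) with crossed random
  intercepts for participant and scene, fitted by REML/ML with a
  profiled-deviance solver, compared incrementally by likelihood-ratio
  tests and AIC, and summarized in predictor decile bins.

Because raw recordings for such studies are typically not deposited, the
package includes a first-class **synthetic cohort generator**
(`socialgaze.simulate`) producing scenes with controlled saliency
structure, ROI masks, and scanpaths (fixation-level or raw 1000-Hz
samples) from a mechanistic gaze model with known ground truth — every
pipeline stage is testable end-to-end without external data. See
`docs/methods.md` for the model and its calibration.

## Worked example

```python
import warnings
warnings.filterwarnings("ignore")
from socialgaze import CohortConfig, run_synthetic_cohort

config = CohortConfig(n_participants=8, n_social=12, n_nonsocial=12, seed=42)
results = run_synthetic_cohort(config)

print(results.paired_tests.round(3).to_string(index=False))
print()
print(results.roi_participant_density.groupby("roi")["rel_norm_density"]
      .mean().round(2).to_string())
print()
head = results.timecourse_roi.query("roi == 'head'")
print(head.groupby("rank")["norm_freq"].mean().round(1).to_string())
```

prints (≈40 s):

```
metric  mean_social  mean_nonsocial       t  df     p  d_paired
  d_kl        1.615           0.974  22.751   7 0.000     8.044
   auc        0.759           0.798  -6.021   7 0.001    -2.129
     r        0.171           0.717 -44.368   7 0.000   -15.686

roi
body      3.92
head      9.31
higher    1.02
lower     0.38

rank
1      1.0
2     30.5
3     18.9
4      8.7
5      8.2
6+    11.2
```

Reading the output: saliency predicts fixations *worse* in social scenes —
divergence D_KL is higher (paired d = 8.0) while AUC and r are lower. Gaze
is allocated to heads ~9× more than their area predicts, with the ordering
head > body > higher-saliency > lower-saliency. And although heads lie
~9.6° from the starting position — about two average saccades away — head
fixation frequency is near zero at fixation 1, peaks at fixation 2, and
declines afterwards: the two-saccade signature of reflexive social
orienting. (Magnitudes vary with cohort size; the full 31 × 160 default
sharpens every test.)

The same pipeline runs from the command line:

```bash
socialgaze generate-cohort --output cohort/ --seed 1      # scenes, masks, gaze.tsv
socialgaze run-all --output results/ --seed 1             # all stage CSVs + manifest
socialgaze detect-events --gaze cohort/gaze.tsv --output events.tsv
```

For real data, supply saliency maps as float TIFF (any saliency model),
ROI masks as indexed PNG (0 background, 1 head, 2 body), and gaze as TSV
(`participant_id  scene_id  t_ms  x_px  y_px  pupil_valid`); an
EyeLink-ASC-style sample reader is included.

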