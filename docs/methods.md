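# Methods

## The measurement model

One observation is a three-channel fluorescence picture of a single
pancreatic islet: a DAPI layer showing all nuclei, a 488 layer carrying a
β-cell membrane/cytoplasm marker (TMEM27, BACE2 or insulin), and a 555
layer carrying an α-cell counterstain (glucagon). The islet boundary is
given externally as a binary mask — automated islet segmentation is
deliberately out of scope, because segmentation error would confound the
group comparisons the score feeds into. All intensities are rescaled to
[0, 1] by the image dtype maximum at load time, so every threshold in the
pipeline is bit-depth independent.

The per-islet pipeline is:

1. **Nucleus detection** (DAPI). The layer is smoothed with a Gaussian of
   σ = min_radius/2, foreground is separated with the same histogram
   k-means used for staining (below), connected components smaller than
   π·min_radius²/4 px are discarded as debris, and touching nuclei are
   split by watershed on the distance transform seeded at local maxima at
   least min_radius apart. A nucleus belongs to the islet iff its centroid
   lies on a mask pixel. The detector is classical and fully
   deterministic; its parameters are the credible nucleus radius range
   (defaults 3–8 px at quarter scale).
2. **Stain/background separation** (488 and 555 independently). The
   count-weighted 256-bin histogram of the *whole image* is clustered with
   1-D k-means, k = 2: centres start at the 10th and 90th percentile of
   the occupied intensity range and Lloyd iterations run to movement
   < 1e-6 (≤ 100 iterations); no random restarts, so the result is
   reproducible. The pixel threshold is the left edge of the first bin of
   the upper cluster, making the stained-pixel set exactly a union of
   histogram bins; a test verifies on every fixture that this equals the
   global within-cluster-sum-of-squares optimum found by exhaustive
   boundary search (in 1-D the optimal two-cluster partition is always a
   threshold). Images whose histogram occupies a single bin, or whose
   final centres are closer than two bin widths, are flagged degenerate
   and scored all-background — islets with no detectable marker expression
   must legitimately score 0.
3. **Cell classification.** For each nucleus, stained pixels of each
   channel are counted in a disc of patch_radius (default 2.5·min_radius)
   around the centroid, clipped at the image border; the strict majority
   between the 488 and 555 counts labels the cell β or α. Ties — including
   zero evidence in both channels — are left unclassified; unclassified
   cells count toward the nucleus total but not toward β-density.
4. **Features.** The area score is
   3 · |stained ∩ islet ∖ nuclei| / |islet|: nuclei pixels are excluded
   from the numerator only, the denominator being the full islet area (the
   alternative, excluding nuclei from both, is available as the
   `denominator="islet_minus_nuclei"` switch). The ×3 map is the linear
   [0,1] → [0,3] rescaling that makes the automated score commensurate
   with the pathologist's scale. Islet size is the mask pixel count, and
   β-cell density is n_β per islet area, reported per 10⁴ px² and per mm²
   when a pixel size is supplied. Intensity values never enter the final
   estimator directly — only through the stained/background decision —
   which is what makes the score robust to staining-strength variation
   between slides.

A surrogate of the manual score is provided for method-comparison
experiments: intensity level (0–3) × stained-cell fraction, rounded
half-up to 0.25 steps. The pathologist's actual decision tree combines the
two factors in a way that is not fully specified, so the surrogate is a
documented approximation, not a claim of equivalence.

## Cohort statistics

Per-islet features are aggregated per patient and marker by the median
(even counts: mean of the two middle values). Group contrasts use the
pooled-variance unpaired two-tailed t-test (a Welch option exists but is
off by default, matching the classical "Student" convention).
Associations are Pearson correlations reported as r² with two-tailed p
from the t distribution on n−2 df. Slope differences between the ND and
T2D groups (e.g. score vs BMI) use ANCOVA fitted as a single OLS model
`y ~ 1 + g + x + g·x`; the per-group slope estimates then equal the
within-group least-squares slopes exactly and the interaction t-test
(n−4 df) is the slope-difference p. No multiple-testing correction is
applied; p < 0.05 is the significance convention. All estimators are
implemented from the normal equations (scipy supplies only the t tail)
and are tested for ≤ 1e-8 agreement against scipy/statsmodels, keeping
implementation and oracle independent. Clinical-table summaries report
per-group means and sample standard deviations (ddof = 1) of age and BMI
and per-marker islet totals; the packaged 60-patient table reproduces
every printed aggregate exactly (its footnote's non-diabetic source
counts disagree with the table body; the body is authoritative here).

## Synthetic data

The generator emulates the imaging model the pipeline assumes: an
elliptical islet (default semi-axes 105×145 px on a 344×258 canvas —
quarter scale of the native 1376×1032 acquisition format, for speed; full
scale is a parameter change), Gaussian-profile nucleus blobs (radius 3 px,
peak 0.9, σ = radius/2), a stained cytoplasmic annulus (width 3 px) per β
cell in the 488 layer and per α cell in the 555 layer, stain level 0.7
over background 0.1, a low-order polynomial multiplicative illumination
field (default amplitude 0.2, exercising the illumination-robustness
claim), and additive Gaussian noise (default σ = 0.10; the recovery tests
use σ = 0.15, i.e. signal-to-noise (0.7−0.1)/0.15 = 4). Ground truth
(centres, classes, pre-noise stain masks, the exact stained fraction) is
recorded before degradation. "Well-separated" placement enforces a centre
distance of 2·(nucleus_radius + annulus_width) so neighbouring annuli are
disjoint and the patch vote has unambiguous truth. Defaults of 40 nuclei
per islet keep cells well separated for testability; real islets are far
more densely packed, so passing tests demonstrate correctness of the
algorithmic steps, not segmentation performance on confluent tissue.

For score-recovery experiments a target-fraction mode replaces the
488 annuli: stained discs are placed at random inside the islet, kept at
least 1.75·nucleus_radius away from every nucleus centre, and trimmed to
exactly ⌈f·area⌉ pixels. The margin keeps detected nucleus regions (which
extend to ≈1.2·radius under the adaptive threshold) disjoint from true
stained pixels, which is why noise-free recovery is exact to pixel-count
resolution. With noise at SNR 4 the k-means threshold sits at the WCSS
optimum, which for strongly unbalanced classes lies closer to the
background mode; at f = 0.1 this inflates the score noticeably (mean
error ≈ 0.25 score units) while f ≥ 0.3 recovers to within a few
hundredths — the grid-mean absolute error is ≈ 0.08, within the 0.15
recovery bound. This bias is a property of two-means thresholding itself
under heavy noise, not of the implementation; at the generator's default
noise (SNR 6) it disappears (mean error ≈ 0.003).

Synthetic cohorts draw per-islet area scores around group means (ND 1.8,
T2D lower by the effect size; defaults 0.8 score units of effect, 0.3
between-islet SD, 20+20 patients, 9 islets each, matching the study's
typical islet count per patient and marker) with per-patient BMI from
group-specific normals mirroring the clinical table (ND 26±3, T2D 30±4
kg/m²). Scores are clipped to [0, 3] (negligible at the default means),
and an optional BMI-slope couples score to BMI for regression
experiments. Patient latent means equal the group mean, so patient
medians are i.i.d. within group and the null t-test calibration
(≈5% rejections at α = 0.05) is exact by construction.

## Numerical choices and edge cases

- Histogram domain is always [0, 1] over the whole image (not just the
  islet): background outside the islet informs the background cluster,
  and islet restriction happens at counting time.
- Lloyd assignment uses "strictly above the centre midpoint"; an emptied
  cluster or near-coincident centres short-circuit to the degenerate map.
- Disc patches and stained-disc stamps use exact Euclidean membership
  (`(i−r)² + (j−c)² ≤ R²`) and are clipped at image borders.
- Empty islet masks are rejected at construction; an all-background islet
  legitimately scores 0 with zero β-cells.
- Centroid rounding for islet membership clamps to image bounds.
- Feature CSVs are written at 8 significant digits and round-trip to
  better than 1e-6.
- Per-islet seeds in the CLI and acceptance script derive from the master
  seed by a fixed affine map modulo 2³¹, so every run is reproducible from
  one integer.

## Problem sizes

The test suite and acceptance script run everything at the quarter-scale
canvas: 100 islets for score recovery (5 fractions × 20 seeds), 6 islets
for detection/classification recovery, 50 histogram fixtures for the
threshold oracle, 1000 replicates for t-test calibration and 100 synthetic
cohorts per effect size for power — sizes chosen so the complete suite
runs in well under a minute per stage on a single CPU while keeping
Monte-Carlo standard errors a few percent at most.

## Known limitations

- No photorealistic microscopy effects (PSF, chromatic shift, autofluorescence,
  exocrine background texture); robustness claims extend only to the
  modelled degradations (Gaussian noise, smooth multiplicative illumination).
- The nucleus detector is tuned for well-separated, roughly circular
  nuclei; densely packed or elongated nuclei will be under-split.
- The manual-score surrogate approximates an incompletely specified
  scoring tree.
- Whole-image histograms assume the field of view is dominated by a
  bimodal stain/background mixture; a slide with three distinct intensity
  populations would need k > 2, which is out of scope.
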