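# isletquant

Automated, unbiased quantification of pancreatic islet features from
three-channel immunofluorescence images.

Assessing β-cell loss in type 2 diabetes from histology is slow and
subjective when done by eye: a pathologist scores each islet on a [0, 3]
scale combining staining intensity with the percentage of stained cells, and
staining is highly heterogeneous between islets of the same patient. This
package implements an automated replacement for that manual score. Given a
fluorescence picture with a DAPI nuclear layer, a 488 β-cell-marker layer
(e.g. TMEM27, BACE2 or insulin) and a 555 α-cell counterstain layer (e.g.
glucagon), plus a pathologist-drawn islet mask, it computes per islet:

- **area score** — the fraction of islet pixels (nuclei excluded) classified
  as stained, rescaled linearly to [0, 3]: `score = 3 · |stained ∩ islet ∖
  nuclei| / |islet|`;
- **islet size** — mask area in px² (µm² when the pixel size is known);
- **β-cell density** — cells voted β-positive per unit islet area.

The pixel classifier needs no per-image threshold: a 1-D two-cluster k-means
on the count-weighted intensity histogram splits each channel into staining
and background adaptively, which also makes the score robust to smooth
illumination gradients. Nuclei are detected on the DAPI layer (smoothing,
adaptive thresholding, distance-transform watershed) and each nucleus is
called α or β by majority vote over stained 555/488 pixels in a patch around
it. A cohort layer aggregates per-islet features to per-patient medians and
provides the accompanying statistics: Pearson correlation (reported as r²),
the unpaired two-tailed Student t-test, ANCOVA slope comparison between
patient groups, and clinical-table summaries. A seeded synthetic-data module
generates islet images and cohorts with full ground truth, so the whole
pipeline is testable end to end without patient material.

Intended users: image-analysis and diabetes researchers quantifying
endocrine marker expression in tissue sections, and anyone needing a
deterministic, auditable replacement for manual immunofluorescence scoring.

## Worked example

```python
import isletquant as iq

params = iq.SynthParams(seed=42, noise_sd=0.1)       # synthetic islet, known truth
stack, islet, truth = iq.generate_islet(params)
features = iq.score_islet(stack, islet)
```

Running `python examples/score_synthetic_islet.py` (the same computation)
prints:

```
islet area:            47824 px
area score:            0.145  (truth 0.149 on the [0,3] scale)
beta cells detected:   28  (truth 28)
alpha cells detected:  12  (truth 12)
beta-cell density:     5.85 per 10^4 px^2
```

The area score recovers the generator's true stained fraction (0.149 × 3
scale) to within a few hundredths despite additive noise and a 20%
illumination gradient, and all 40 cells are detected and correctly
classified. The other scripts in `examples/` demonstrate the adaptive
thresholding, the synthetic cohort statistics (t-test and ANCOVA on patient
medians), and the packaged 60-patient clinical table, whose per-marker islet
totals (TMEM27 528, BACE2 541, insulin 905; 1974 overall) are reproduced by
direct aggregation.

## Command line

```sh
isletquant synth  --out demo -n 5 --seed 7          # images + masks + truth
isletquant score  --out features.csv -i demo/islet_000.tif -m demo/islet_000_mask.png
isletquant cohort --cohort cohort.csv --features features.csv --out report
```

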