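# aortagrad

Automatic quantification of aortic contrast enhancement from CT pulmonary
angiography (CTPA), and the small-cohort statistics needed to relate it to
clinical outcomes in acute pulmonary embolism (PE).

In acute PE, contrast medium reaches the aorta only after passing the
pulmonary circulation and both sides of the heart, so the *pattern* of
enhancement along the thoracic aorta carries hemodynamic information: a
compromised circulation lets the bolus stall proximally, producing a
steeper intensity decline towards the diaphragm. This package turns that
idea into numbers and tests it.

## What it computes

**Imaging.** Given a CT volume with binary aorta and lung masks (NIfTI;
e.g. produced by any segmentation tool), the pipeline

1. truncates the aorta at the diaphragm (the lowest axial plane containing
   lung voxels) and locates two landmarks: the *endpoint* (aorta centroid
   on that plane) and the *startingpoint* (ventral centroid on the lowest
   plane where ascending and descending aorta appear as two distinct
   cross-sections);
2. extracts a centerline between the landmarks (medialness-weighted
   shortest path on the mask, smoothed and resampled at 1 mm);
3. straightens the vessel by curved planar reformatting with
   rotation-minimising frames and computes, in every perpendicular plane,
   the mean intensity inside a circular ROI (half the local inscribed
   lumen radius);
4. fits an ordinary least-squares line to the profile of ROI means against
   the position normalised to 0–100 % of the aorta length, giving three
   markers per patient:

   * **mean intensity** (HU) — mean of the per-plane ROI means,
   * **proximal intensity** (HU) — the fitted intercept I(0), enhancement
     at the aortic root,
   * **contrast gradient** (HU/%) — the fitted slope, reported per
     10-unit decrease so that the odds ratio below reads naturally.

**Statistics.** Because adverse outcomes are rare in such cohorts (a few
events per outcome), logistic modelling uses **Firth's penalized
likelihood**, which maximises ℓ(β) + ½·log det I(β) and stays finite under
complete separation. Model building mirrors the clinical analysis:
simple linear regressions flag anatomical/acquisition confounders (lung
volume, aorta length/volume/diameter, contrast delay); forward selection
by **penalized likelihood-ratio (PLR)** tests adds predictors at entry
level α = 0.05 (the reduced model of each test is a constrained fit with
the candidate's coefficient fixed at 0 under the full design's penalty);
**Benjamini–Hochberg FDR** adjusts the selected predictors' p-values
across the family of outcome models; cross-tabulation metrics
(sensitivity, specificity, PPV, accuracy at probability cutoff 0.5), ROC
points and nested PLR comparisons benchmark the gradient against the
binary clinical markers (hemodynamic instability, RV/LV > 1).

**Synthetic ground truth.** No patient data ship with the package.
`generate_phantom` builds a candy-cane aorta (half-torus arch + straight
descending tube) with lungs, a linear HU trend plus periodic fluctuation
and noise, and an analytic truth record; `generate_cohort` draws patient
tables from a logistic model with known coefficients, a left-skewed
gradient distribution, bimodal intensities and correlated confounders.
Every pipeline stage is validated against these truths.

## Worked example

```bash
python examples/01_phantom_to_parameters.py
```

```
Ground truth : intercept 350.0 HU, slope -0.800 HU/%, length 245.7 mm
Measured     : proximal intensity 353.9 HU, contrast gradient -0.880 HU/%
               mean intensity 309.9 HU, gradient per 10 units -8.80
Centerline   : 245.0 mm (0.29% from the analytic arc length)
Dimensions   : aorta volume 111.9 mL, mean diameter 23.9 mm, lung volume 0.58 L
```

The phantom's lumen follows I(s) = 350 − 0.8·s plus a 20 HU periodic
fluctuation and 5 HU noise; the pipeline recovers the slope to within the
perturbation caused by the fluctuation (noise-free phantoms recover it to
well under 1 %). `examples/02_cohort_statistics.py` runs the full
statistics on a synthetic cohort and prints, per outcome, the per-10-unit
odds ratio with its CI, Wald p and FDR-adjusted q next to the generating
truth; `examples/03_firth_under_separation.py` shows the Firth estimate
staying finite (and matching a brute-force grid maximiser) under complete
separation.

A thin CLI wraps the same library calls:

```bash
aortagrad phantom --out phantom_dir
aortagrad imaging --manifest manifest.json --out imaging_dir
aortagrad stats --params parameters.csv --cohort cohort.csv --out stats_dir
```

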