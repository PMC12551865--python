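# Methods

## Scope and data model

The package quantifies contrast enhancement along the thoracic aorta from
a CTPA volume plus binary aorta and lung masks, and analyses the resulting
per-patient markers against binary clinical outcomes. Segmentation itself
is out of scope: masks are an input contract. All volumes are reoriented
to a canonical RAS frame on load (nibabel `as_closest_canonical`), so
"inferior" always means a smaller index along the third array axis and
"ventral/anterior" a larger anterior world coordinate; phantom volumes are
generated directly in that frame.

## Imaging chain

**Truncation and landmarks.** The thoracic aorta is delimited by the
diaphragm, operationalised as the lowest axial plane containing lung
voxels; aorta planes inferior to it are discarded. The *endpoint* is the
integer-rounded centroid of the aorta cross-section on that plane; the
*startingpoint* is found by scanning planes from inferior to superior for
the first one on which the aorta splits into exactly two 8-connected
components of at least 25 mm² each (the area threshold suppresses
segmentation specks; it is configurable) and taking the centroid of the
more anterior component. Centroids that fall outside the mask (possible
for crescent-shaped sections) snap to the nearest in-mask voxel on the
plane.

**Centerline.** Between the landmarks a shortest path is computed by
Dijkstra's algorithm over 26-connected in-mask voxels with edge cost
`step_length / (inscribed_radius + ε)`, where the inscribed radius is the
Euclidean distance transform of the mask (mean of the two end voxels,
ε = 0.5 mm). The medialness weight pulls the path onto the vessel axis:
on a torus-shaped lumen the cost of a circular path at arch radius R − δ
is proportional to (R − δ)/(r − δ), which is minimised at δ = 0, i.e. on
the medial circle. The voxel path is smoothed by a moving average with a
window of about one lumen radius (the median inscribed radius along the
path), endpoints re-anchored to the landmarks, and resampled uniformly at
1 mm. A 1 mm step resolves a 250–350 mm vessel amply and is finer than a
typical reconstruction increment. On the noise-free phantom this
centerline reproduces the analytic arc length πR + L to about 0.3 %.

**Measurements (confounders).** Aorta length is the centerline arc
length; aorta volume is voxel count × voxel volume; lung volume likewise
(in litres). Mean aorta diameter is twice the mean inscribed radius
sampled along the centerline, after trimming one median radius from each
end where the distance transform measures the distance to the axial cut
rather than to the vessel wall. No operational definition of "diameter"
is universal; the averaged distance-transform definition is a stated
choice of this package.

**Straightening and profile.** At every centerline point a square plane
perpendicular to the local tangent is resampled by trilinear
interpolation, with the in-plane grid at the volume's minimum voxel
spacing and in-plane axes propagated by double-reflection
rotation-minimising frames (avoiding torsion-induced frame flips on the
arch; plane half-width default 20 mm). The per-plane ROI is a disc
centred on the centerline point with radius `roi_fraction` (default 0.5)
times the local inscribed lumen radius. That radius is measured
*in-plane*, as the distance from the plane centre to the nearest
out-of-lumen sample of the reformatted mask, rather than from the 3D
distance transform: at the aortic root and the diaphragm the 3D transform
measures the distance to the axial cut and would collapse the ROI on the
first and last planes, whereas the perpendicular cross-section there is a
full disc. The 0.5 fraction keeps the ROI clear of the partial-volume rim
and of wall calcification. An ROI radius below one sample spacing is an
error ("ROI unresolved").

**Line fit.** Plane positions are normalised so the first plane is 0 and
the last 100 (planes are uniformly spaced in arc length, so index- and
arc-length-normalisation coincide). An unweighted ordinary least-squares
line of ROI mean on position yields the proximal intensity (intercept)
and contrast gradient (slope, HU/%); the mean intensity is the arithmetic
mean of the per-plane ROI means (not volume-weighted). The gradient is
additionally reported per 10 units, matching the conventional odds-ratio
scale. A periodic fluctuation A·sin(2πfs/100) with integer cycle count is
nearly orthogonal to the linear trend, perturbing the fitted slope by less
than |A|/25 on 200 planes; correcting the fluctuation itself is out of
scope.

## Statistics

**Confounder scan.** Each of the three markers is regressed on each of
the five confounders (lung volume, aorta length/volume/diameter, contrast
delay) by simple linear regression with list-wise exclusion per pair,
reporting R², slope with 95 % CI and the F-test p-value; confounders
significant (p < 0.05) for any marker become covariates of the outcome
models.

**Firth penalized logistic regression.** With only a handful of events
per outcome the unpenalized MLE is biased and diverges under separation,
so all outcome models maximise the Jeffreys-penalized log-likelihood
ℓ(β) + ½ log det I(β) by Newton iteration on the Firth-modified score
(residuals y − π + h(½ − π), with h the hat diagonal), with step-halving
whenever a step would decrease the penalized likelihood. Convergence is
declared at max |score| < 1e-10 (tight enough that intercept-only fits
reproduce the closed form (k + ½)/(n + 1) to ~1e-9 on the probability
scale) within 100 iterations. Standard errors come from the inverse
Fisher information at the optimum; Wald p-values are two-sided normal.
Odds-ratio CIs are Wald intervals exponentiated from the β scale.

**PLR tests and forward selection.** A penalized likelihood-ratio
statistic 2(ℓ*_full − ℓ*_reduced) is only chi-square calibrated when both
likelihoods share the same Jeffreys penalty; the ½ log det I term itself
grows with the design dimension and covariate scale, so comparing two
independently penalized fits of different dimension systematically
inflates the statistic. The reduced model is therefore a *constrained*
fit: the dropped coefficients are fixed at 0 while the penalty is still
computed from the full design (the approach used by penalized-likelihood
software such as `logistf`). Under this convention a pure-noise predictor
is rejected at very close to the nominal 5 % (measured ≈ 4–5 % over 1000
replicates). Forward selection adds, at each step, the remaining
candidate with the smallest PLR entry p-value while it is below
α_entry = 0.05 (ties broken by candidate order, logged); entry p-values
of never-entered candidates are reported from the terminating step, and
each final model is compared to the constant-only model by the same
constrained PLR (the model chi-square).

**Multiplicity.** BH step-up FDR adjustment is applied to the Wald
p-values of all selected predictors across the outcome models fitted in
one run; that family choice is logged with the results. Adjusted values
follow q_i = min over dominating raw p of min(1, p·m/rank).

**Diagnostics.** 2×2 cross-tabulations give sensitivity, specificity,
PPV and accuracy in percent (model-based predictions binarised at
probability 0.5 by default); the association p-value is a Pearson
chi-square without continuity correction, replaced by Fisher's exact test
when any expected cell count is below 5 (the choice of test is a package
convention — the original analyses do not name one). ROC points are
computed at every distinct fitted probability. List-wise exclusion is
applied per analysis throughout; no imputation is performed.

## Synthetic data

**Phantom.** The candy-cane geometry (half-torus arch of radius 40 mm
joined to a 120 mm straight descending tube, lumen radius 12 mm, on a
1.5 mm isotropic grid by default) is the minimal shape with a curved and
a straight segment, exercising the rotation-minimising frames and the
two-component landmark logic. The descending tube continues 15 mm below
the diaphragm plane so truncation removes a real piece, as with a
segmented scan; the ascending root is cut flat at the arch-hinge level so
the lowest two-component plane coincides with the analytic root. Lumen
voxels carry I(s) = I0 + g·s + A·sin(2πfs/100) + N(0, σ²) with s the arc
position normalised to 0–100 % between root and diaphragm; defaults
I0 = 350 HU, g = −0.8 HU/%, A = 20 HU, f = 5 cycles, σ = 5 HU emulate a
well-opacified aorta with the periodic fluctuation seen in real profiles
(vena-cava/spine artifacts and wall calcium). Background is soft-tissue
40 HU, lungs −800 HU. The truth record stores the analytic centerline,
arc length, intercept/slope and both landmark voxels.

**Cohort.** Markers are drawn directly from distributions shaped like the
observed histograms: proximal intensity from a two-component Gaussian
mixture (modes 320/430 HU), mean intensity as proximal − 40 HU plus
noise (strongly correlated, likewise bimodal), and the gradient as
2 − LogNormal(log 8, 0.5) HU/%, i.e. left-skewed with mode ≈ −4 and SD
≈ 4.8. The gradient scale is chosen so that the documented per-10-unit
effect sizes are informative at realistic cohort sizes; the histograms it
imitates publish no axis scale, so these parameters are stated, not
matched. Confounders load linearly on the intensity level and (weakly,
negatively) on the gradient, reproducing the observed sign pattern
(negative slopes except contrast delay vs the intensity markers) at R²
values around 0.05–0.2. Outcomes are Bernoulli draws from
logit⁻¹(a + β·gradient); the intercept a is solved per outcome so the
expected prevalence over the generated gradients matches the target
(defaults: the 93-patient cohort prevalences, with the five short-term
outcomes carrying the reported per-10-unit coefficients ÷ 10 and all
others null). Hemodynamic instability and RV/LV > 1 are generated the
same way with negative gradient coupling. Missingness is completely at
random: each patient is incomplete with probability `missing_rate`
(default 0.03) and then has one uniformly chosen outcome cell blanked, so
the expected number of incomplete rows is n × rate.

What the generators do *not* emulate: real anatomy and branch vessels,
bolus physics, scanner protocol effects, partial-volume blur beyond
voxelisation, non-random missingness, and any dependence of the intensity
markers on the confounders other than linear-Gaussian coupling. Passing
tests therefore demonstrate correctness of the measurement and inference
machinery under known ground truth, not clinical validity on real scans.

## Problem sizes and numerical choices

The test and acceptance runs use a compact phantom (2 mm grid, arch
radius 35 mm, 100 mm descending segment) where many phantoms are needed,
and the default 1.5 mm phantom for geometry checks; selection behaviour
is measured on 40–50 cohorts of 2000 patients and null calibration on
400–500 cohorts of 400. These sizes give Monte-Carlo error comfortably
below the asserted margins. Ties in forward selection resolve by
candidate order; degenerate inputs (constant response with predictors,
zero-variance regressors, all-equal profile positions, empty planes)
raise explicit errors rather than returning NaNs. Random number streams
are `numpy.random.default_rng` seeded per spec field or derived from the
acceptance script's `--seed`.

## Known limitations

* The centerline is a medialness-weighted shortest path, not a
  vascular-modelling-toolkit centerline; on real, branchy anatomy the two
  may differ near the root and at strong calcifications.
* The periodic fluctuation is measured but not corrected; it perturbs the
  fitted slope by up to |A|/25 even in the ideal case.
* The per-10-unit odds-ratio scale follows the conventional reporting of
  this marker; interpreting it requires knowing the cohort's gradient
  dispersion, which real studies rarely publish.
* The FDR family (selected predictors across the models of one run) is
  one of several defensible choices; with rounded inputs different
  families give slightly different adjusted values.
* Diagnostic metrics of rare outcomes at cutoff 0.5 are dominated by the
  all-negative prediction regime (sensitivity 0, specificity 100); they
  are reported for comparability, not as a recommended operating point.
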