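# Methods

## The measurement model

The pipeline treats three per-subject images, all pre-registered to one
common grid (registration/normalisation is an upstream concern; mismatched
grids are refused, never resampled):

* a modulated grey-matter (GM) volume map from a VBM-style preprocessing,
* a tau-PET SUVR image (or dynamic frames plus a reference-region mask),
* and shared masks: a GM analysis mask and an integer-labelled atlas.

**SUVR.** Dynamic frames are averaged with duration weights over the
acquisition window (80–100 min, or 80–90 min for short scans), then divided
by the mean activity in the reference mask (inferior cerebellar grey
matter in the emulated protocol). Motion and partial-volume correction are
assumed already applied upstream.

**Smoothing.** Each SUVR image is smoothed with the anisotropic Gaussian
kernel matched to its scanner — FWHM 6.55 × 6.55 × 7.75 mm (x, y, z) for the
PET/CT tomograph, 7.37 × 7.37 × 7.91 mm for the HRRT — so the two scanners'
effective resolutions agree; σ per axis = FWHM / (voxel size · √(8 ln 2)).
The default boundary rule renormalises the truncated kernel over the
in-mask support (`smoothed = G∗(mask·f) / G∗mask`), which preserves
constants exactly and avoids attenuating SUVR near the brain edge;
SPM-style zero-padding is available by flag. Order is fixed: smooth, then
threshold — the two do not commute, and a regression test pins the order.

**Positivity.** A GM voxel is tau-positive when its smoothed SUVR ≥ 1.30.
The comparator is configurable (`ge`/`gt`) because primary sources disagree
between "> 1.30" and "≥ 1.30"; the default is `ge`, which only affects
voxels exactly at the threshold. % positivity of any region is
100 · |positive ∩ region| / |GM ∩ region|; missing voxels belong to neither
mask and are excluded from every count, with the effective n reported.

**Normative w-scores.** For each voxel v in the fit mask, GM volume in
healthy controls is regressed on [1, age, TIV] by OLS; the residual SD uses
the unbiased n − 3 denominator (the denominator convention is not dictated
by any source; n − 3 is the standard unbiased choice). A subject's w-score
is (observed − predicted) / residual SD. Age and TIV are z-scaled
internally for conditioning only — w-scores are invariant to any affine
covariate rescaling (property-tested to 1e-8). Voxels with residual SD
below a configurable floor (default 1e-6 GM units) are excluded from maps
and summaries to avoid division blow-up at near-deterministic voxels.
Subjects whose covariates fall outside the control range (± a 10% guard
band) are scored with a warning, never silently. Subjects with an empty
tau-positive mask contribute no paired observation; the count is logged.

**Inference.** The paired t-test on per-subject (mean w in tau+, mean w in
tau−) uses the n − 1 SD and a t reference with n − 1 df; a degenerate
zero-variance difference is flagged rather than reported as an infinite t.
Partial Pearson correlations residualize both variables on
[1, age, education, scanner, scan-window] by least squares; r is the
correlation of residuals with df = n − 2 − k. Scanner and window enter as
0/1 indicators (partial correlation is invariant to affine recoding, so the
coding is immaterial). All p-values are two-sided. Bonferroni families are
always explicit: 6 for the composite × tau-measure table (3 composites × 2
measures), the number of regions tested for the quartile table.

**BCa bootstrap.** Confidence intervals use the bias-corrected accelerated
bootstrap: z0 from the fraction of bootstrap statistics below the point
estimate (with a half-weight for ties and clipping to (1/(B+1), B/(B+1))),
acceleration from the jackknife skewness formula, and the adjusted normal
percentiles applied to the bootstrap distribution. Resampling can be
stratified (used with quartile groups, preserving group sizes); a statistic
undefined on a resample triggers a redraw, with more than 10% redraws
fatal. With z0 = a = 0 forced, the interval reduces exactly to the
percentile interval — a self-check in the suite. Every bootstrap call takes
an explicit seed. Default repetition counts follow the two contexts the
design prescribes: 2000 for the paired difference and the quartile
regressions, 1000 for the composite correlation table.

**Quartiles.** Subjects are rank-split by global % positivity into four
groups (quartile 1 = lowest burden). The split depends only on ranks
(invariant to monotone transforms); ties break by subject id, and when n is
not divisible by 4 the larger groups go to the lower quartiles, so n = 47
gives 12/12/12/11. Region-wise regressions use extent (positive-voxel
count) on [1, quartile (numeric 1–4), age, scanner, window]; quartile as a
numeric predictor matches the "increase across quartiles" question, with
dummy coding available. Per-region % positivity is also emitted for use as
an alternative dependent variable.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes —
not anatomy. Defaults are the study conditions throughout the test suite:

* **Controls** (n = 54, ages uniform 26–71, TIV ~ N(1500, 120²) mL):
  GM map = a fixed smooth baseline template (sum of low-frequency cosines,
  mean level ≈ 0.55 in GM-probability-like units) + β_age·(age − 48.5) +
  β_TIV·(TIV − 1500) + N(0, σ_GM²) per voxel, with β_age = −0.002/yr,
  β_TIV = 2·10⁻⁴/mL, σ_GM = 0.04. The template is an analytic function of
  voxel coordinates, so no external brain template is ever needed.
* **Athletes** (n = 52 screened, ages ~ N(51, 14²) truncated to 24–85):
  SUVR = 1 + s_i·E(v) + N(0, 0.08²), where E(v) is a fixed tau-excess field
  — an anterior/lateral-weighted diffuse component (amplitude 0.38, with a
  central depression keeping deep grey quiet) plus four compact
  radial-cosine hotspots (peaks 0.50/0.375) — and s_i ~ U(0.7, 1.3) is a
  per-subject severity factor. Severity is what gives the cohort a tau
  *gradient*; without it the quartile analysis and the memory correlation
  would be degenerate. GM = control-model prediction +
  coupling_beta · max(SUVR − 1, 0) + noise, coupling_beta = −0.040 GM units
  per SUVR-excess unit.
* **Neuropsych**: the three memory z-scores are constructed so their mean
  is exactly memory_slope · (global % positivity) + N(0, memory_sigma²)
  (slope −0.018 z/%, σ 0.8), with within-subject jitter that sums to zero;
  speed and executive inputs are drawn independently of tau (null domains).
* **Biofluids**: each athlete gets one assay (30% in-house plasma, 38% V2
  plasma, 32% CSF); a chosen fraction (default 4/52) receives values above
  their assay's threshold with a stated margin, the rest below; the
  generator records its own labels so the gate can be verified exactly. One
  further athlete (the highest-severity gate-negative subject) carries an
  AD-like tau-PET-pattern flag, reproducing the 52 → 47 screening
  arithmetic.
* **Acquisition mix**: 66% PET/CT / 34% HRRT; 78.7% long window.

Everything is deterministic given the config seed, via independent RNG
substreams per stage; changing the seed changes noise realisations only.

### Calibration of the coupling defaults

The source analysis reports the paired w contrast only as observed cohort
means (≈ −0.37 in tau-positive vs −0.31 in tau-negative voxels), not as a
generative effect size, so the coupling scale is the implementer's choice.
The defaults above were fixed by a one-off calibration (12 seeds,
16³ grid) targeting that magnitude: they yield mean w ≈ −0.39 in
tau-positive and ≈ −0.21 in tau-negative voxels, a memory partial r ≈
−0.32 to −0.42, global % positivity ≈ 20 ± 16%, non-empty tau-positive
masks for all 47 included athletes, and exactly zero positive voxels in
the deep negative-control regions. The tau-negative mean is shallower than
the target because a hard SUVR threshold separates high- from low-excess
voxels more cleanly in a smooth synthetic field than in real data; pushing
the sub-threshold excess high enough to deepen it would have flooded the
deep negative-control regions. The contrast direction, its
within-subject pairing, and the quartile spatial gradient — the properties
the tests assert — are preserved.

### What the generator does not emulate

Real anatomy and folding geometry, scanner noise physics and resolution
nonuniformity, off-target tracer binding, site/batch effects, covariate
confounding between severity and age, and longitudinal change. Passing
tests therefore demonstrate that the *pipeline* measures what it claims
under its stated assumptions — not that those assumptions hold in any real
cohort.

## Statistical calibration findings

Held-out control calibration (fit on 100 controls, score 100 independent
controls, 16³ grid) gives w-scores with grand mean ≈ 0.001 and SD ≈ 1.03,
as a correctly specified normative model should (SD slightly above 1
reflects prediction variance at finite n).

One genuine subtlety, measured and kept: because every athlete is scored
against the *same* estimated normative model, their w-score errors share
the model's estimation error, which makes the paired t-test mildly
anticonservative at the study's sample sizes — with 54 controls the null
rejection rate at α = 0.05 is ≈ 0.08 (800 replicates), returning to ≈ 0.04
when the control sample is large (n = 500). This is a property of the
w-score paired design itself (any study with ~50 controls and ~50 scored
subjects inherits it), not of this implementation; the memory partial
correlation, whose null does not involve the normative model, rejects at
the nominal rate (≈ 0.04). The pipeline reports the test as specified and
documents the inflation here rather than silently "correcting" it.

## Problem sizes

Default simulations use a 16³ grid (≈ 1640 GM voxels), 54 controls and 52
athletes — small enough that the full chain runs in well under a second,
chosen so the replicate studies in the test suite (100 power replicates,
500 null replicates, 1000-repeat bootstrap-coverage Monte Carlo) complete
in a couple of minutes while keeping every estimate's Monte-Carlo error
well inside the asserted bands. All operations are grid-size-agnostic.

## Known limitations

* The Aβ42/t-tau index formula is not uniquely determined by the source
  protocol; the Hulstaert discriminant is the default and the index is
  pluggable. Boundary cases near index = 0.8 depend on this choice.
* Quartile tie-breaking by subject id is deterministic but arbitrary;
  heavily tied % positivity values (e.g. many subjects at exactly 0) make
  group membership order-dependent in exactly the way the logged warning
  states.
* The executive composite includes digit span backwards as a third element
  alongside the WCST average and TMT-B; the source description is elliptical
  on this point, and the choice is configurable.
* The paired test's mild anticonservatism at small control samples is
  documented above; a corrected test (e.g. accounting for shared model
  error) would depart from the published procedure and is out of scope.
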