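# tauvbm

Repetitive head impacts in contact sports are associated with tauopathies
such as chronic traumatic encephalopathy, but whether in-vivo tau-PET signal
in retired athletes marks tissue that is actually degenerating is an open
question. `tauvbm` implements, end to end, an analysis that asks exactly
that: in a cohort of retired contact-sport athletes screened *negative* for
Alzheimer-type pathology, do tau-PET-positive grey-matter voxels show more
atrophy than tau-PET-negative voxels, and does global tau burden track
memory performance?

Because the underlying human imaging data are not public, the package ships
a first-class synthetic cohort generator with known ground truth, so every
stage — and the full chain — is testable: effect sizes are recovered, null
configurations reject at the nominal rate, and every counting primitive is
checked against brute-force enumeration.

## The analysis

1. **Biofluid gate.** Athletes are screened for Alzheimer-type pathology:
   plasma p-tau181 (in-house Simoa assay: positive if > 10.5 pg/mL under age
   60, > 13.3 pg/mL at 60+; commercial V2 kit: > 2.2 pg/mL) and/or CSF
   (positive if p-tau > 68 pg/mL and Aβ42/t-tau index < 0.8, with the index
   defaulting to Aβ42 / (240 + 1.18·t-tau)). Positivity on any modality at
   any visit, or an AD-like tau-PET retention pattern, excludes the subject.
2. **Tau-PET positivity.** SUVR images (inferior-cerebellar reference;
   duration-weighted frame averaging over the 80–100 or 80–90 min window)
   are smoothed with scanner-matched anisotropic Gaussian kernels
   (PET/CT: 6.55×6.55×7.75 mm FWHM; HRRT: 7.37×7.37×7.91 mm), then
   thresholded at SUVR ≥ 1.30 inside a grey-matter mask.
   % positivity = 100 · (positive voxels) / (grey-matter voxels), globally
   and per atlas region.
3. **Normative w-scores.** A voxelwise OLS of grey-matter volume on age and
   TIV, fit on healthy controls, yields per-voxel coefficients and residual
   SDs. An athlete's w-score at a voxel is
   `w = (observed − predicted(age, TIV)) / SD(control residuals)` —
   lower w means less grey matter than expected for that age and head size.
4. **Inference.** Mean w inside each athlete's tau-positive and tau-negative
   masks are compared by paired t-test with a BCa bootstrap CI on the mean
   difference; tau measures (% positivity, mean SUVR) are related to memory,
   speed and executive composites by Pearson partial correlations
   (controlling age, education, scanner, scan duration) with BCa CIs and
   Bonferroni correction; and the cohort is split into % positivity
   quartiles, with region-wise regressions of positive-voxel extent on
   quartile group and age locating where the signal spreads.

## Worked example

The numbered drivers under `analysis/` run the chain on a simulated study
(54 controls, 52 screened athletes, 16³ grid), writing tables under
`results/`:

```sh
python analysis/01_simulate_cohort.py      # volumes + tables -> results/cohort/
python analysis/02_screen_biofluids.py
python analysis/03_pet_positivity.py
python analysis/04_neuropsych_composites.py
python analysis/05_normative_wscores.py
python analysis/06_quartile_spatial.py
python analysis/07_inference.py
```

With the default seed this prints, among other lines:

```
screened 52 athletes: 5 excluded (4 plasma, 0 CSF, 1 PET pattern), 47 included
47 athletes: global % positivity mean 18.7%, SD 15.4%, range 0.2-48.3%
47 athletes: mean w in tau+ voxels -0.412 ± 0.161, in tau- voxels -0.214 ± 0.037
quartile sizes (12, 12, 12, 11), interior cuts at 3.2%, 15.9%, 30.7%
steepest quartile increase: anterior_left_superior (+46.0 voxels/quartile, BCa [43.1, 48.8]);
8/12 regions significant after Bonferroni; deep negative-control regions max |coef| = 0.00
mean w: tau+ -0.412 ± 0.161 vs tau- -0.214 ± 0.037 (paired p = 2.8e-10,
BCa 95% CI of the difference [-0.250, -0.153])
```

Reading this: the biofluid gate removed the 5 planted screening positives;
tau-positive tissue carries distinctly lower age/TIV-adjusted grey-matter
volume than tau-negative tissue within the same subjects; the signal climbs
across quartiles in the anterior/lateral cortical regions where the
generator planted it while the deep "hippocampus-like" negative-control
regions stay flat — the spatial pattern the analysis is designed to detect.

The same chain is available as a CLI (`tauvbm run --out dir --seed 1`, plus
per-stage subcommands `simulate`, `gate`, `composites`, `pet`,
`fit-normative`, `wscore`, `quartiles`, `analyze`) and as a library
(`tauvbm.pipeline.run_pipeline`).

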