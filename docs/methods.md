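# Methods

`dmnrv` implements a resting-state fMRI analysis that relates within-network
coherence of the default mode network (DMN) to cerebrospinal-fluid (CSF)
biomarkers of the Alzheimer's continuum, together with a synthetic-cohort
generator that makes every stage of the analysis testable against planted
ground truth.

## The connectivity statistic

For an ROI `R` with voxels `v_i(t)` and mean time course
`m(t) = mean_i v_i(t)`, the **ROI-to-voxel (RV) correlation** is

    RV(R) = median_i  z( corr(v_i, m) ),     z(r) = atanh(r)

— the median Fisher-z of each voxel's Pearson correlation with its own
region mean: a within-region coherence statistic. Correlations are clipped
at `|r| = 1 − 1e−7` before the transform (degenerate, perfectly coherent
regions stay finite and ordered; clips are logged), voxels with a flat time
course (max = min) are excluded from the median and counted, and an even
voxel count takes the mean of the two central z values.

Ten metrics are reported per subject over the anterior, posterior, and
ventral DMN subregions:

* four **RV ("Median") metrics** — `Median posterior`, `Median ventral`,
  `Median average` (RV of the union of all three subregions against the
  union's own mean time course), and `Median anterior-posterior` (RV of the
  anterior∪posterior union);
* six **RV ratios** `X to Y = RV(X) / RV(Y)` over the ordered pairs
  (anterior|average) × (average|posterior|ventral) plus
  posterior-to-ventral. The anterior/posterior ratio is the classic DMN
  RV-ratio; the other pairs generalize the same single combination rule
  (division). Ratios are exactly transitive:
  `(a/p)·(p/v) = (a/v)` to machine precision.

An alternative reading of "X to Y" — the Fisher-z of the correlation
between X's and Y's mean time courses — is available as
`compute_metric_table(..., mode="timecourse")` for sensitivity analysis; it
is not the default because the ratio reading follows the only combination
rule the RV framework defines.

## Preprocessing

Input volumes are assumed spatially aligned (registration is out of scope;
the generator produces aligned data). The chain, in order:

1. **discard** the first `k = 3` volumes (T1 equilibration);
2. **smooth** each volume with an isotropic Gaussian, FWHM 4 mm
   (σ = FWHM ⁄ 2√(2 ln 2), converted to voxels; zero-padded boundaries —
   edge voxels are biased, so fixture ROIs sit ≥ 2 voxels from the edges);
3. **detrend**: remove the per-voxel least-squares line (closed-form
   projection, identical to the normal equations);
4. **bandpass** 0.01–0.08 Hz with an *ideal rectangular DFT filter*: bins
   with `low ≤ f ≤ high` kept, everything else (including DC) zeroed.
   This dialect (rather than an IIR design) matches the classic
   resting-state toolkits and is exactly idempotent, which makes the filter
   contract testable to 1e−10;
5. **nuisance regression**: per-voxel least-squares residual on an
   intercept, six motion regressors (used as provided, no derivatives), and
   the top 5 white-matter and 5 CSF principal-component time courses
   (CompCor convention; the count is configurable) extracted from the
   *filtered* series, so nuisance removal is self-consistent with the
   temporal filtering.

Numerical notes. Detrend and the bandpass are non-commuting projections: a
band-limited series retains a small sample linear trend, so a second
detrend+bandpass pass changes the series by ~1% at T = 300 (shrinking
roughly as 1/T). The pipeline therefore guarantees exact idempotence of the
filter itself, not of the composed pair. Likewise, regressing 17 nuisance
columns from band-limited data (few effective in-band degrees of freedom)
perturbs RV slightly even when nothing was planted — about 0.04 z-units at
the default series length.

## Statistics

* **Demographics table**: age, MMSE, and education are routed through a
  Shapiro–Wilk gate (α = 0.05, per group; "normal" only if both groups
  pass): t-test with mean (SD) summaries when normal, Mann–Whitney U with
  median (IQR) otherwise (exact enumeration when the combined n ≤ 20 and
  tie-free, tie-corrected normal approximation otherwise). Sex uses an
  asymptotic chi-square on the 2×2 counts (Fisher exact on request). MMSE
  banding follows the conventional cut-offs (≥24 normal, 19–23 mild,
  10–18 moderate, ≤9 severe).
* **Associations**: for every group × biomarker × metric cell, (a) the
  partial Pearson correlation of biomarker and metric given age and sex
  (residualize both, correlate residuals; p from t with n − k − 2 df) and
  (b) an OLS fit of the metric on the biomarker plus age and sex, reporting
  R², the standardized β of the biomarker (x and y z-scored, covariates
  unscaled), and the two-sided p of its coefficient. Both p-values are the
  same t-test and agree to 1e−10 — a property the suite asserts. Education
  is deliberately *not* adjusted for: the adjustment set is age and sex
  only, mirroring the analysis this package reproduces, despite the groups
  differing in education.
* **Multiple comparisons**: Benjamini–Hochberg step-up within each
  (group, biomarker, statistic-kind) family of ten metric tests — the
  column structure of the result tables; `fdr_family="table"` widens the
  family. Significance stars mark FDR-adjusted p < 0.05 / 0.01 / 0.001.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
the physics of fMRI:

* **Atlas**: disjoint axis-aligned boxes for anterior/posterior/ventral DMN
  plus WM and CSF compartments on a 20×20×10 grid of 3 mm voxels (4³-voxel
  ROIs). A 12×12×10 variant with 3³ ROIs serves the Monte-Carlo studies.
* **BOLD**: per subject and region, a coherence parameter
  `c ~ U(0.3, 0.9)` and a unit-variance band-limited (0.01–0.08 Hz) region
  signal `s_R(t)`; each voxel is `√c·s_R + √(1−c)·ε_i` with white
  unit-variance `ε_i`. The wide c range makes between-subject coherence
  differences dominate estimation noise — the regime an individual-
  differences analysis needs. Contamination is then added: per-voxel linear
  drift (slope sd 0.5 signal units over the scan), six standardized
  random-walk motion regressors with random per-voxel loadings (amplitude
  0.3), and WM/CSF compartment-signal leakage into every voxel (amplitude
  0.3); the WM/CSF boxes carry their compartment signal so CompCor can find
  it. The exact motion series are exported as the subject's nuisance file.
  Everything is reproducible from (seed, subject index) via independent
  RNG substreams, so a subject's data do not depend on cohort ordering.
* **Phenotypes**: groups CN (n = 25) and MCI (n = 23); ages
  N(70.62, 5.34²) / N(72.77, 5.75²); sex 15F/10M and 11F/12M (0 = female —
  a single binary covariate matches an age-and-gender adjustment);
  education and MMSE drawn to match the reference medians/IQRs. CSF
  biomarker levels are built per group as `r·z + √(1−r²)·η` (η iid
  standard normal) and mapped to pg/mL with plausible location/scales
  (GAP-43 5500 (2000), Aβ1–42 180 (50), t-tau 90 (35), p-tau181 30 (12));
  `r` comes from the effect map, whose defaults plant the reported
  qualitative structure: +0.491 for CN GAP-43, −0.590 for MCI t-tau, and
  −0.582 for MCI p-tau, all on "average to posterior", with no amyloid
  effect.
* **The effect driver `z`** is the *model-implied asymptotic metric value*:
  with long series and many voxels, a voxel's correlation with its region
  mean tends to √c, and with an equal-sized-union mean to
  `c_R/√(Σ c)`, so e.g. the driver of `Median posterior` is
  `atanh(√c_post)` and the driver of `average to posterior` is the ratio of
  the corresponding asymptotic RVs. Coupling biomarkers to this truth-side
  quantity (never to the measured RV) means observed associations are
  attenuated exactly by measurement reliability — which the validation
  studies measure rather than assume.

What the generator does **not** emulate: rigid-body head motion (motion is
purely additive regressor contamination), scanner drift nonlinearity,
spatial autocorrelation of noise, hemodynamic response shape, assay noise
models for the biomarkers, or any registration error. Passing tests
therefore demonstrate that the *estimators and statistics* behave correctly
under the assumed signal model, not that the pipeline is robust to real
acquisition artifacts.

TR and series length are not reference-pinned; defaults are TR = 3 s and
T = 140 volumes (common resting-state conventions), both configurable. A
series must cover at least two cycles of the lowest passband frequency
(T ≥ 2/(0.01·TR)).

## Validation studies (problem sizes)

The acceptance suite and `scripts/acceptance.py` run four studies:

* **Filter probes**: sinusoids at 0.005/0.04/0.20 Hz, TR = 2 s, T = 300;
  passband gain ≥ 0.95, stopband ≤ 0.05.
* **Null calibration**: 200 cohorts with all effects zero (compact grid,
  T = 120, full contamination and preprocessing); mean per-family raw
  rejection at α = 0.05 should sit near 0.05 and FDR-significant cells at
  or below 0.05.
* **Effect recovery**: 200 cohorts with r = 0.5 planted on
  `Median posterior` in CN (n = 25), contamination-free BOLD; the mean
  estimated partial r equals planted r × the coherence-to-RV reliability
  (measured alongside, ≥ 0.9 in this regime), i.e. ≈ 0.47 — attenuation is
  explained, not hand-waved.
* **Sign pattern**: 50 cohorts at the *full defaults* (default atlas,
  T = 140, default contamination) with the default effect map; the
  estimated partial correlations carry the planted signs in ≥ 90% of
  replicates pooled over the three planted cells, and the amyloid cells
  show no systematic effect. At these noise levels the measured reliability
  of the ratio metric is ≈ 0.6, so the expected per-cell agreement is
  ≈ 0.92–0.95; the pooled rate is the stable summary at 50 replicates.

## Known limitations

* The "ventral" region, the "average" aggregate, and the "X to Y" naming
  are reconstructions of an under-specified metric family; the ratio
  reading is the default and the time-course-correlation reading is kept as
  a config switch, but neither can be verified against the original
  implementation.
* The RV ratio is unstable when the denominator RV is near zero (the code
  refuses |RV| < 1e−12); with the default coherence range this never
  occurs, but near-incoherent real data could make ratio metrics wild.
* Group sizes of 25/23 give limited power; planted effects below |r| ≈ 0.4
  are frequently non-significant after FDR in a single cohort — consistent
  with how sparse the significant cells are in the tables this layout
  mirrors.
* The Mann–Whitney exact branch only engages for combined n ≤ 20 without
  ties; demographic variables at n = 48 always use the tie-corrected
  asymptotic path.
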