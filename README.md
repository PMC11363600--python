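# dmnrv

Resting-state fMRI connectivity of the default mode network (DMN) and its
association with CSF biomarkers, as a tested, reusable pipeline — with a
synthetic-cohort generator so that every stage can be validated against
planted ground truth, no subject data required.

## What it computes

The central statistic is the **ROI-to-voxel (RV) correlation**: for an ROI
with voxels `v_i(t)` and mean time course `m(t)`,

```
RV(R) = median_i z( corr(v_i, m) ),    z(r) = ½ ln((1+r)/(1−r))
```

— the median Fisher-z of each voxel's Pearson correlation with its own
region mean, a within-region coherence measure. Ratios of RV values between
DMN subdivisions (e.g. the anterior/posterior **DMN RV-ratio**) complete a
set of ten per-subject metrics over the anterior, posterior, and ventral
DMN.

Around that statistic the package provides:

* **Preprocessing** for spatially aligned 4D NIfTI BOLD: initial-volume
  discard, 4 mm Gaussian smoothing, linear detrend, ideal 0.01–0.08 Hz DFT
  bandpass, and CompCor-style nuisance regression (6 motion regressors +
  white-matter/CSF principal components).
* **Association statistics** for two groups (cognitively normal, CN, vs
  mild cognitive impairment, MCI): Shapiro–Wilk-gated demographics
  comparison, partial correlations of each CSF biomarker (GAP-43, Aβ1–42,
  t-tau, p-tau181) with each metric controlling for age and sex,
  age/sex-adjusted linear models (R², standardized β), and
  Benjamini–Hochberg FDR correction per result-table column.
* **A synthetic cohort generator**: band-limited, region-coherent BOLD with
  a planted per-subject coherence parameter c, drift/motion/compartment
  contamination, and biomarker values coupled to the planted connectivity
  at configurable effect sizes (defaults: GAP-43 +0.491 in CN, t-tau −0.590
  and p-tau −0.582 in MCI, on the average-to-posterior ratio; no amyloid
  effect).

See `docs/methods.md` for the model, its assumptions, and what the
synthetic data do and do not emulate.

## Worked example

Run the full pipeline — simulate, preprocess, score, associate — on one
synthetic cohort (25 CN + 23 MCI, compact grid):

```python
from dmnrv import RunConfig, run_pipeline
from dmnrv.synthetic import CohortSpec, compact_atlas_spec

config = RunConfig(cohort=CohortSpec(n_timepoints=120),
                   atlas=compact_atlas_spec(),
                   out_dir="demo_run", seed=42)
report = run_pipeline(config)
print(report.recovery)
```

```
{'corr_c_posterior_vs_Median posterior': 0.9721697546940468,
 'corr_c_ventral_vs_Median ventral': 0.8624622634515727}
```

The recovery summary correlates each subject's *planted* posterior/ventral
coherence with the *measured* RV metric: 0.97 and 0.86 here, i.e. the
pipeline tracks the ground truth it was handed. `demo_run/` now contains
the fixture set, preprocessed series, `metrics.csv`, and the association
tables. A slice of `table2.csv` (partial correlations, stars mark
FDR-adjusted p < 0.05):

```
                           GAP-43 CN  Tau MCI P tau MCI
anterior to posterior          0.379  -0.638*   -0.630*
average to posterior           0.241   -0.325    -0.462
posterior to ventral          -0.419   0.549*     0.392
Median posterior              -0.477   0.559*     0.495
```

The planted negative tau and p-tau couplings surface with the right signs
in the MCI column; in a single cohort of n = 23, sampling noise spreads
significance across the strongly inter-correlated ratio metrics, which is
exactly why the package's validation works with replicate averages rather
than single cohorts.

The same run is available from the shell:

```
dmnrv run --out demo_run --seed 42
dmnrv simulate --out fixtures --seed 7        # fixtures only
dmnrv preprocess --in fixtures --atlas fixtures/atlas.nii.gz --out clean
dmnrv connectivity --in clean --atlas fixtures/atlas.nii.gz --out metrics.csv
dmnrv associate --metrics metrics.csv --pheno fixtures/phenotypes.csv --out tables
```

Re-running with the same config and seed reproduces every output
byte-for-byte; deleting one stage's outputs recomputes only that stage.

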