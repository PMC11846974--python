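# dbmcov

Whole-brain structural-covariance and trajectory analysis of
deformation-based morphometry (DBM) Jacobians, with censoring-aware survival
and motor-behavior statistics — the analysis stack used to characterize
sex-specific neurodegeneration in longitudinal mouse MRI studies of
alpha-synuclein (PFF-inoculation) models, rebuilt as a tested, reusable
pipeline and exercised end-to-end on a synthetic cohort generator with known
ground truth.

## What it computes

Given per-subject-per-timepoint log-Jacobian volumes (local volume change
relative to a template), a brain mask, and cohort/behavior tables:

1. **Matrix preparation** — blur (Gaussian FWHM in mm), invert so atrophy is
   positive, z-score each voxel, shift to non-negativity: an m x n voxel x
   subject matrix.
2. **Orthogonal projective NMF** — X ~= W H with H = W^T X, W >= 0 and
   orthogonal columns, so each voxel belongs to one spatial covariance
   pattern; subject weights H say how strongly each subject expresses each
   pattern. Granularity k is chosen by split-half stability (matched-component
   cosine across subject splits) balanced against the reconstruction-error
   gradient.
3. **Pattern overlap** — binarized (argmax-ownership) maps compared with
   Dice's kappa, `kappa = 2a / (2a + b + c)`, e.g. between sex-specific and
   all-subjects decompositions.
4. **Voxel-wise trajectories** — `volume ~ group * sex * dpi + (1 | subject)`
   at every voxel via a vectorized random-intercept REML engine, with
   Benjamini-Hochberg FDR across voxels.
5. **Survival & motor statistics** — Cox proportional hazards for humane-
   endpoint survival and for latency tasks with hard cutoffs (wire hang:
   fall = event, 150 s cap censored; pole: descent = event, failures
   censored), Bonferroni across the task battery, mixed models for weight
   and rotarod, GLM for motor-onset day.

The synthetic module generates the whole study — planted spatial components,
group x sex x dpi loading effects, hazard-linked attrition, capped behavioral
latencies — so every stage can be validated against ground truth.

## Worked example

The `analysis/` scripts run the full study on one synthetic cohort
(48 mice, 12/sex/group, scans at -7/30/90/120 dpi, 6 planted components):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_assemble_matrix.py
python analysis/03_opnmf_stability.py
```

prints, among other things:

```
cohort: 48 mice (12/sex/group), 8 humane endpoints before 130 dpi
matrix: 3112 in-mask voxels x 42 subjects (0 zero-variance voxels dropped)
 k  stability   error  error_gradient
 2     0.5565 262.754             NaN
 4     0.7589 196.255         -66.498
 6     0.9500 130.027         -66.228
 8     0.6619 127.918          -2.110
10     0.6640 126.905          -1.013
selected k = 6 (planted ground truth: 6 components)
```

Stability peaks (0.95) at the planted granularity and the error gradient
flattens beyond it, so k = 6 is selected. Continuing,

```sh
python analysis/04_sex_pattern_overlap.py
python analysis/05_voxelwise_trajectories.py
python analysis/06_survival_motor_stats.py
```

identifies the PFF-differentiating component in the all-subjects, male-only
and female-only decompositions (group p = 0.016 / 0.008 / 0.027, pooled-SD
Cohen's d = 1.2 / 1.4 / 1.0) and their Dice-kappa overlaps; recovers the
planted group x dpi atrophy voxel-wise (78.5% sensitivity inside the planted
supports, 0.59% discoveries outside, at 1% FDR); and reproduces the
behavioral phenotype (wire-hang failure HR for PFF rising from ~4 at 30 dpi
to ~120 at 120 dpi, pole-test success HR falling to 0.06, both Bonferroni-
significant; inverted-U weight trajectory p = 4e-7). Each script writes its
tables under `results/`.

The same stages run as one reproducible pipeline from a config:

```sh
dbmcov all --out run1 --seed 1          # simulate + prep + OPNMF + stats
dbmcov stability --matrix X.npy --kmin 2 --kmax 20 --step 2 --splits 5 --seed 1
```

`run1/report.json` then contains every statistic, the selected k, and the
kappa table; two runs with the same config and seed produce identical
reports.

## Layout

```
src/dbmcov/        library: synthetic, prep, opnmf, overlap, mixedlm,
                   voxelstats, behavior, nifti_io, config, pipeline, cli
analysis/          numbered narrative scripts (simulate ... survival stats)
tests/             pytest suite, including end-to-end validity checks
docs/methods.md    models, assumptions, parameter choices, limitations
```
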