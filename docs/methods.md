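# Methods

This note documents the models implemented in `dbmcov`, the choices made
where the methodology left room, and what the synthetic validation does and
does not establish.

## Input data model

The pipeline consumes deformation-based morphometry (DBM) derivatives: one
log-transformed Jacobian-determinant volume per subject-timepoint on a common
template grid, plus a brain mask. A log-Jacobian of 0 means no local volume
change relative to the template; negative values are contraction (atrophy).
Two flavors are kept separate throughout: *relative* Jacobians (nonlinear
deformations only) feed the longitudinal voxel-wise models; *absolute*
Jacobians (including residual global scaling) feed the cross-sectional
covariance decomposition. Registration and template construction are upstream
of this package.

Volumes are smoothed with a separable Gaussian kernel specified as FWHM in mm
(default 0.085 mm, sigma = FWHM / (2 sqrt(2 ln 2)) per axis, reflective
boundaries so the volume mean is conserved). A kernel under 0.1 voxel FWHM is
treated as the identity with a warning.

For the decomposition, in-mask voxels of each scan form the columns of an
m x n matrix which is sign-inverted (atrophy positive), z-scored per voxel
(population SD; zero-variance voxels dropped and counted), and shifted by one
global scalar so its minimum is exactly 0. Inversion-by-negation and the
single additive shift are this package's choices (both invertible and
recorded on the matrix object, so the transform can be undone exactly);
clipping was rejected because it destroys variance asymmetrically.

## Orthogonal projective NMF

The decomposition approximates the non-negative matrix X (voxels x subjects)
as W H with H = W^T X (projective form) and W n x k non-negative with
near-orthonormal columns, so that each voxel belongs to essentially one
spatial component. The solver has two phases:

1. **Multiplicative phase.** Yang-Oja-style projective updates
   `W <- W * (X X^T W) / (W (W^T X)(X^T W))`, evaluated without forming the
   m x m Gram matrix, followed by whole-matrix spectral normalization (the
   projective objective fixes the overall scale; per-column normalization
   would distort it). Initialization is deterministic NNDSVD (zeros filled
   with the matrix mean); a seeded uniform random init is available. The
   Frobenius reconstruction error ||X - W W^T X|| is tracked every iteration
   and is empirically monotone; a guard stops the run if a step ever
   increases it beyond 1e-12 relative.
2. **Partition phase.** Voxel exclusivity is then enforced exactly: given a
   disjoint voxel partition, the projective objective decouples and each
   block's optimal component is its leading left singular vector
   (non-negative by Perron-Frobenius). Alternating this exact solve with
   optimal row reassignment (a spherical k-means step in the component row
   space) is monotone; it is run from two seedings — the multiplicative
   solution's argmax labels and a k-means++ row clustering — and the better
   result is returned. The final W therefore has *exactly* disjoint supports
   and unit-norm columns, with the scale carried in H = W^T X.

The soft multiplicative iterate can reach slightly lower error (~1% on noisy
problems) at the cost of 30-40% off-diagonal mass in W^T W; since the
method's premise is that a voxel loads on one component, the strictly
orthogonal solution is returned, and the reported error trace is truncated
where the soft relaxation descends below the error the orthogonal model class
can achieve. Stopping: relative error change below `tol` (default 1e-5),
stalling of the partition solution (checked every 250 iterations), or
`max_iter` (default 10,000).

## Granularity selection

Stability analysis re-runs the decomposition on disjoint half-splits of the
subjects (5 splits per granularity, stratified by sex x injection group when
available) for k = 2..20 in steps of 2 (configurable). Components of the two
half-solutions are matched one-to-one by maximizing total cosine similarity
(Hungarian assignment); stability(k) is the mean matched cosine over splits.
The full-matrix reconstruction error per k yields the error gradient
(difference from the previous granularity).

The default selection rule returns the smallest k whose stability is at
least 0.9 of the maximum *and* whose forward accuracy gain — the error drop
obtained by moving to the next granularity — is at most the median absolute
gradient. Intuition: pick the smallest stable granularity beyond which added
components buy little accuracy. A rule phrased on the backward gradient
(error(k) - error(k-step)) systematically overshoots by one step, because the
granularity where structure is exhausted still has a large backward drop.
The rule is pluggable and the full stability/error table is always reported.
With a single-entry profile that k is returned; if no k qualifies, the most
stable k is returned with a warning.

## Pattern overlap

Component maps are binarized by per-voxel argmax ownership of the W rows
(ties to the lowest index, all-zero rows excluded and counted) — consistent
with the decomposition's voxel exclusivity and threshold-free. Overlap
between two binarized patterns A and B is Dice's kappa,
kappa = 2a / (2a + b + c) with a = |A and B|, b and c the voxels unique to
each; kappa is defined as 0 when both sets are empty. The sex-overlap report
binarizes the group-differentiating component of the all-subjects, male-only
and female-only decompositions — by default the component whose subject-weight
GLM shows the smallest injection-group p — and tabulates the three pairwise
kappas.

## Voxel-wise trajectory models

The longitudinal model at every voxel is

    volume ~ group * sex * dpi + (1 | subject)

with group (PFF vs PBS control) and sex (M vs F) as indicators and dpi (days
post-injection) continuous. Because the fixed design is shared across voxels,
the model is fit by a dedicated vectorized engine: the profiled REML
criterion of the single-random-intercept model reduces, via the Woodbury
identity, to group-wise sums that are evaluated for all voxels simultaneously
on a log-spaced grid of the variance ratio sigma_b^2/sigma_e^2 (121 points
over 1e-5..1e5 plus 0), refined per voxel by parabolic interpolation. This
is exact for the model family and agrees with a general mixed-model fitter to
~1e-5 relative on the coefficients (cross-checked in the tests); fitting 10^3
voxels takes ~60 ms.

Wald t statistics use containment degrees of freedom: between-subject terms
(those constant within subject) against n_subjects - p_between, within-subject
terms against N - n_subjects - p_within — exact for balanced designs, an
approximation under attrition; df below 1 falls back to the normal. Voxels
with non-finite statistics are flagged and excluded from correction, never
silently dropped. Per-term p-values are corrected across voxels by
Benjamini-Hochberg (default q = 0.01), which matches brute-force step-up
enumeration (verified exhaustively on short p-vectors).

Post-hoc GLMs on the decomposition's subject weights fit
`weight ~ group * sex` by OLS, dropping the interaction with a warning when a
cell is empty. Cohen's d uses the pooled-SD formula (ddof = 1 within groups);
every report carries the variant tag, since d values from different pooling
conventions are not comparable.

## Survival and motor behavior

Latency tasks have hard cutoffs, so means are not estimable without bias and
all task inference is censoring-aware Cox proportional hazards
(partial likelihood, Efron ties):

- **wire hang** (150 s success cap): the *event* is a fall before the cap;
  holding to the cap is censored.
- **pole test** (120 s failure cap): the *event* is a successful descent;
  failures are censored at their recorded time.
- **survival**: the event is the humane endpoint; mice alive at the
  experimental end (130 dpi) are censored. Kaplan-Meier curves are exported
  per sex x group cell.

Each trial is one record with trial number and body weight as covariates (no
frailty term); the default formula is `~ group * sex + trial + weight`.
Zero-event tables are refused with a clear error; convergence failures
(separation) raise with advice to penalize. Note that when no control animal
dies, the group main effect in the survival model is separated and its Wald
statistics are meaningless — the fit is still reported because the
interaction may remain estimable.

Family-wise error across the motor battery (2 latency tasks x 4 timepoints)
uses Bonferroni at p < 0.05/8 with strict inequality at the boundary.
Longitudinal weight and rotarod (trials averaged per timepoint first) use the
same random-intercept engine as the voxel-wise analysis; an optional
quadratic-dpi coding captures inverted-U weight trajectories. Motor-onset dpi
among symptomatic mice is an OLS GLM on group * sex, with single-level
factors dropped (in practice only PFF mice become symptomatic) and one-mouse
cells flagged.

## Synthetic study generator

The generator emulates the data *structure* of a longitudinal PFF-inoculation
study, with every stage's ground truth known:

- **Design**: balanced sex x injection cells (default 15/cell, i.e. ~30 per
  injection group), scans at -7, 30, 90, 120 dpi, 0.1 mm isotropic voxels.
- **Survival**: exponential proportional hazards with log-linear predictor
  `group + sex + group:sex` (defaults: baseline 8e-5/day so controls
  essentially all survive; PFF log-HR 2.3 plus 1.3 extra for male PFF,
  giving ~30% male-PFF mortality by 120 dpi), administratively censored at
  130 dpi; scans and trials after a subject's endpoint do not exist.
- **Images**: log J = -(sum of loading_c x component_c) + Gaussian scan noise
  (SD 0.05). Loadings follow a linear model in group, sex and dpi (the
  group:dpi slope 0.003/day gives ~25% peak volume loss by 90-120 dpi in the
  affected parcels, with an extra male-PFF acceleration) plus a per-subject
  random expression (SD 0.15) held fixed over time — the source of structural
  covariance, set well above scan noise as in real morphometry. The absolute
  flavor adds a per-subject global size offset (SD 0.05). dpi enters the
  generating model linearly including the -7 baseline, keeping it identical
  to the analysis model so slope-recovery checks are exact.
- **Spatial components**: two layouts. The default *tiling* layout partitions
  the whole mask into k0 smooth disjoint parcels (nearest-seed regions of
  well-separated template directions), emulating whole-brain covariance
  parcellations. The *blobs* layout plants compact isolated lesions in an
  unstructured background (template placement on sphere directions with
  seeded jitter; explicit error when the grid cannot host k0 disjoint blobs)
  and is used for focal-atrophy recovery and null-calibration experiments.
  Supports are pairwise disjoint in both layouts, mirroring the
  decomposition's voxel exclusivity.
- **Behavior**: three trials per surviving subject-timepoint-task. Latencies
  are log-normal with group x dpi location shifts; scoring follows the task
  rules (pole failures record the 120 s cap; wire-hang times at or above the
  cap record 150 s as successes; rotarod has no cutoff). The wire-hang cap
  defaults to 150 s — the recorded maximum — although the protocol is
  sometimes described with a 3-minute cutoff; the cap is a parameter. For
  planted-hazard-ratio experiments the wire-hang generator switches to an
  exponential proportional-hazards latency model (`ph_hr`), because an exact
  planted log-HR is only defined under proportional hazards; the log-normal
  default is an accelerated-failure-time family.

What the synthetic validation shows: the decomposition recovers constructed
orthogonal factorizations exactly; stability-based selection finds a planted
granularity; the voxel-wise engine is calibrated under the global null
(false-discovery proportion at the nominal level) and recovers planted
atrophy with high spatial specificity; Cox fits recover planted hazard
ratios at the stated precision; the whole pipeline is bit-reproducible under
a fixed seed. What it does not show: robustness to registration error,
spatially correlated or non-Gaussian noise, non-linear trajectories,
informative censoring, or real anatomical covariance — none of which the
generator emulates.

## Problem sizes and numerics

Default analysis runs use a 20^3 grid (~3,100 in-mask voxels) with 12 mice
per cell; calibration suites use ~10^3-voxel masks with 40 subjects and
hundreds of replicates — sizes chosen so the full analysis and test suite
re-run comfortably on a laptop-class single core while keeping every
statistical check well-powered. All randomness flows from explicit seeds
(`numpy.random.default_rng`); stage seeds are derived, never shared between
stages. Matrix inversions go through solves; reconstruction errors are
computed via Gram identities and clamped at zero; multiplicative updates
guard denominators at 1e-12.
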