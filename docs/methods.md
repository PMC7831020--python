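# Methods

## Analysis model

`bmmap` operates on per-patient binary lesion masks that share one template
grid (after registration and segmentation, which are outside this package's
scope), plus an integer-labeled region atlas on the same grid with per-region
laterality (left / right / midline) and tentorial compartment
(supratentorial / infratentorial).

### Lesion labeling and localization

Distinct lesions are maximal connected sets of foreground voxels. The
default connectivity is 26 (any shared face, edge or corner of the voxel
cube), the convention of MATLAB's `bwlabeln`; 6 and 18 are selectable. The
verbal rule "connected through at least one edge" corresponds to
18-connectivity, and which of the two a given legacy analysis used is often
ambiguous — both are exercised by the tests, and the choice is a parameter
everywhere. Labeling itself is delegated to `scipy.ndimage.label` with the
matching structuring element and is verified against a brute-force
flood-fill oracle.

A lesion's centroid is the unweighted mean of its member voxel indices
(voxel-center convention, 0-based). The lesion belongs to the atlas region
at the voxel nearest its centroid (half-integer ties round toward the lower
index); when that voxel is background, the nearest labeled voxel by
Euclidean distance wins, with exact ties broken toward the lowest region id
so assignment is deterministic. Lesions spanning several regions are counted
winner-takes-all; fractional attribution is deliberately not attempted.

Volumes are voxel counts times the single-voxel volume, a configurable
constant defaulting to 0.08 mm³. This number reproduces the arithmetic of
normalized (template-space) volumes in the literature this pipeline follows;
it is smaller than the voxel volume of common 1–2 mm isotropic template
grids, so it should be read as a normalization constant, not a physical
acquisition parameter. Per-patient aggregates: TV = Σ lesion volumes,
VSL = TV / lesion count; region-level VSL averages over the lesions assigned
to that region.

### Frequency and ADIFFI maps

The frequency map sums binary masks voxel-wise, so each patient contributes
at most 1 per voxel. ADIFFI compares two phenotype groups A (n_A) and B
(n_B) per voxel via the 2×2 table (a, b; c, d) = (lesioned A, lesioned B;
lesion-free A, lesion-free B). The two-sided exact p-value is the sum of
hypergeometric point probabilities over all tables with the observed margins
whose probability is ≤ the observed table's (the standard "point-probability"
two-sided convention; ties are kept in the tail with a 1e-9 relative guard
against floating rounding). Voxels lesioned in nobody (or everybody) have a
degenerate margin and get p = 1 with no direction, which makes testing all
voxels equivalent to testing only voxels touched in either group. The
per-voxel computation is memoized over the distinct (a, b) pairs in the map,
so a whole-brain map costs only as many exact tests as there are distinct
tables.

Thresholding is per-voxel at α (default 0.05) with no multiplicity
correction by default, matching the per-voxel convention of lesion-mapping
studies this reproduces; Benjamini–Hochberg FDR across tested voxels is
available but off by default. Significant voxels are clustered per direction
(A-dominant and B-dominant separately) with the same connectivity as lesion
labeling; clusters report size, peak (minimum-p) voxel, per-compartment
voxel fractions against the atlas, and the dominant region.

### Relative metastatic risk

For region x: N_x = number of patients with ≥ 1 centroid-assigned lesion in
x (patients, not lesions), N_p = cohort size, V_x = region volume. The
per-unit-volume rate N_x/N_p/V_x is divided by its arithmetic mean over the
N_R regions, so mean(RMR) = 1 exactly and RMR > 1 flags susceptibility. A
region with zero volume is rejected; a region no patient hits has RMR 0.

### Survival

OS is months from first radiological detection to death (event) or last
follow-up (censored). Kaplan–Meier estimation, log-rank tests (omnibus
χ²_{k−1} plus unadjusted pairwise comparisons when k ≥ 3) and Cox
proportional-hazards regression are delegated to `lifelines`; Cox fits use
Efron's tie approximation (the lifelines default) and reference-coded
factors with the conventional reference levels (young, female, lung primary,
1 lesion, small TV, no infratentorial involvement, no radiotherapy).
Univariate mode fits each factor alone; multivariate jointly. Separation or
non-convergence raises; it is never silently absorbed. Continuous covariates
are dichotomized at in-sample medians unless cut points are configured;
values tied with the median join the "≥ median" group, and a patient with
both supra- and infratentorial lesions counts as infratentorially involved.
Group-location comparisons of lesion metrics use Mann-Whitney U (exact where
SciPy supports it) or Kruskal–Wallis, with a hand-implemented Dunn post hoc
(pooled mid-ranks, tie-corrected variance, Bonferroni adjustment by
default) since no Dunn implementation is part of the dependency set.

## Synthetic cohort

The generator provides the study conditions for every test:

- **Atlas** — an ellipsoidal foreground (semi-axes 90 % of the half-extents)
  partitioned into equal-width z-bands split left/right about the x
  midplane, plus midline regions occupying a central x strip below the
  infratentorial cut. Defaults: 24×28×24 grid, 8 lateral pairs + 2 midline
  = 18 regions, infratentorial fraction 0.25 of the foreground z-extent
  (≈ cerebellum + brainstem share). One interior band edge is snapped to the
  cut so every region is purely supra- or infratentorial.
- **Lesions** — per-patient count: categorical over {1, 2} plus a shifted
  geometric tail (p = 0.5) for ≥ 3, with bin probabilities
  (0.494, 0.170, 0.336); placement region drawn ∝ configurable weights
  (default ∝ region volume, i.e. spatially uniform); center uniform over the
  region's voxels; radius uniform in 1–3 voxels; spheres rasterized by the
  voxel-center-within-radius rule, clipped to the foreground, overlapping
  spheres merging by union (so confluent lesions exercise the labeling
  rule).
- **Covariates** — age N(59.8, 12²) clipped to 16–89 y; male 60.5 %;
  primaries lung 86.1 %, breast 4.2 %, colorectal 2.5 %, head-and-neck
  1.3 %, kidney 1.1 %, melanoma 0.6 %, other 4.2 %; lung subtypes
  adenocarcinoma 66.4 %, small-cell 17.8 %, squamous 11.2 %, other 4.6 %;
  Ki-67 normal around medians 35 % (primary) and 45 % (BM) with SD 15,
  clipped to [0, 100]; treatment categorical over the five surgery/WBRT/SRS
  combinations.
- **Survival** — exponential baseline with hazard ln 2 / 10.84 per month
  (baseline median OS 10.84 months), log-linear effects: hazard ratio 1.473
  for infratentorial involvement (computed from the patient's own rasterized
  lesions, not from the intended placement) and 1.036 / 1.751 for 2 / ≥ 3
  lesions; independent uniform censoring on [0, 72] months. Sex, age and the
  other covariates do not enter the hazard, which makes them planted null
  covariates for coverage checks.

What the generator does **not** emulate: anatomically realistic region
shapes, non-spherical or textured lesions, grey–white-junction and watershed
preference, spatial correlation between covariates and supratentorial
sub-location, and informative censoring. Passing tests therefore demonstrate
the correctness and statistical calibration of the pipeline machinery on
data satisfying its assumptions — not clinical conclusions about real
cohorts.

## Numerical and design choices

- All randomness flows from one integer seed (`numpy.random.default_rng`;
  the pipeline splits per-stage seeds via `SeedSequence.spawn`), making
  reruns byte-identical.
- Exact-test tail inclusion uses a 1e-9 relative tolerance; the exhaustive
  n ≤ 8 sweep agrees with the factorial-formula oracle to < 1e-12.
- Percentages print with one-decimal half-up rounding.
- Problem sizes in the test and acceptance runs — 2000-patient cohorts × 10
  seeds for hazard-ratio recovery, 100 patients per group for
  planted-effect detection, 60 patients for the end-to-end demo — were
  chosen so Monte-Carlo error is small relative to the 3-standard-error
  acceptance bands while a full run stays in the tens of seconds.

## Known limitations

- Registration, segmentation and any image-intensity processing are out of
  scope; inputs must already be binary masks on one grid.
- Cluster inference is per-voxel thresholding; no permutation-based
  cluster-mass control is provided.
- Cox diagnostics are limited to convergence checking; proportionality is
  assumed (and true by construction for the generator).
- Region assignment is centroid-based; a large lesion straddling regions is
  attributed entirely to the centroid's region.
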