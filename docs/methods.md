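# Methods

## The analysis model

The package treats a cohort of patients, each with one or more brain
metastases delineated as binary masks on a common 1-mm isotropic standard
grid, and asks whether the anatomical distribution of lesions depends on a
per-patient group label (here: breast-cancer subtype — luminal A, luminal B,
HER2, TNBC).

Each lesion is reduced to a single point, the unweighted mean of its member
voxels' world coordinates (binary-mass center of gravity). Intensity
weighting is deliberately not used: lesions arrive as binary masks, and the
COG of the mask is the natural "primary site of occurrence". The COG voxel
is assigned to one of eleven anatomical segments by direct atlas lookup;
the 20-mm spheres exist only for the visual frequency map and play no part
in region assignment.

The region × subtype counts are tested with Pearson's chi-square test of
independence, and per-cell deviations are quantified with adjusted
standardized residuals

    r_ij = (O_ij − E_ij) / sqrt(E_ij (1 − n_i·/N) (1 − n_·j/N)).

The (1 − margin/N) terms give the residuals unit variance under
independence, which is what makes a fixed ±1.96 threshold meaningful; plain
Pearson residuals (O−E)/√E are available but are not the flagged quantity.
No multiplicity correction is applied across the 44 cells — the flags are
descriptive follow-up to one global test, not 44 independent hypotheses.

## Conventions and numerical choices

- **Coordinates.** Voxel indices are 0-based; world coordinates are mm via
  the volume's 4×4 affine (RAS for shipped fixtures). World→voxel rounding
  is to the nearest index with exact halves toward the *lower* index — any
  fixed rule works, but it must be one rule everywhere, or region assignment
  can silently shift by a voxel at box boundaries.
- **Sphere membership.** A voxel belongs to a lesion's sphere when its
  center lies within diameter/2 (= 10 mm by default) of the COG voxel's
  center, Euclidean in world mm, with a 1e-9 tolerance so exact-radius
  voxels are included deterministically. On a 1-mm grid the 20-mm sphere
  contains 4169 voxels, 0.47% below the continuum volume 4πr³/3 ≈ 4188.8.
- **Heat map.** Overlapping spheres add (the map counts occurrences); a
  max-projection variant is deliberately not implemented. The map is not
  clipped to a brain mask.
- **Connectivity.** Components default to 26-connectivity, the most
  inclusive standard choice for manually delineated lesions; 6 and 18 are
  available.
- **Out-of-atlas COGs.** A COG on a background voxel takes the label of the
  nearest labelled voxel within 10 mm (exact-distance ties break toward the
  lower label id); farther than that it is "unassigned", logged, and
  excluded from contingency tables with a logged count.
- **Resampling.** Registration transforms are accepted only as plain 4×4
  world-coordinate affines; tool-specific matrix dialects are not parsed.
  The pulled-back voxel mapping is snapped to integers when within 1e-9, so
  identity and whole-voxel translations are exact; trilinear interpolation
  is refused for label volumes.
- **Percentages** are rounded half-up to one decimal (exact decimal
  arithmetic, not float rounding), matching how published tables are
  formatted.
- **Chi-square details.** Empty rows/columns are dropped with a warning
  before testing; Yates continuity correction exists for 2×2 tables but is
  off by default (the headline analysis is a multi-df table). When more
  than 20% of cells have expected counts below 5 — true of the example
  table — a warning is logged and an optional Monte-Carlo p-value
  (multinomial resampling from the fitted independence probabilities) can
  be computed alongside; the analytic p remains the primary result.
  Kruskal-Wallis (tie-corrected, chi-square approximation) is provided for
  cohort covariates; an all-identical sample returns H=0, p=1 rather than
  an error.

## The example dataset

`brainmets.datasets` ships an 11×4 counts table from a 67-patient,
437-lesion breast-cancer cohort, the cohort's symptom breakdown, and a
437-row per-lesion expansion. Two parts of it are reconstructions and are
labelled as such in the code: the symptom table is derived from published
percentages anchored on the seven asymptomatic patients (its "other"
category, 9 patients, is the remainder after the four reported categories),
and the per-lesion records assign lesions to synthetic patient ids
round-robin with COGs at region-box centroids, because no per-patient
lesion listing was ever published. Analyses that stratify by patient would
therefore be fixture-dependent; the contingency analysis, which pools
lesions, is not.

On this table the full 11×4 chi-square gives X² = 53.14, df = 30,
P = 0.0057 (no rows collapsed). The ±1.96 adjusted-residual flags are the
five substantive cells (cerebellum over-represented for luminal A and B,
cerebellum under- plus putamen and thalamus over-represented for HER2, and
nothing for TNBC) *plus* the pineal body / luminal B cell, where a single
observed lesion against an expected 0.14 pushes r to +2.42. That flag is a
mechanical consequence of the residual formula at a near-empty cell, and
the normal approximation is poor there; the package reports it (the
formula is applied uniformly) and leaves interpretation to the analyst.

## The synthetic-cohort generator

`CohortSpec` emulates the statistical structure the analysis assumes:

- **Group sizes** default to 28 / 9 / 14 / 16 patients (luminal A / luminal
  B / HER2 / TNBC), the example cohort's sizes.
- **Lesion counts** per patient follow a zero-truncated negative binomial
  with underlying mean 1.0 and dispersion 0.1. These defaults give a
  per-patient median of 2 lesions with strong over-dispersion (IQR ≈ 1–6).
  A single two-parameter ZTNB cannot match the example cohort's median (2)
  and mean (6.5) simultaneously; the median — the statistic such cohorts
  actually report — was chosen, so simulated cohorts average ≈ 310 lesions
  rather than 437. `fixed_lesion_count` overrides the law for exact-count
  tests.
- **Region preferences** default to the example cohort's per-subtype
  distributions; `null_cohort_spec()` gives all subtypes the overall
  437-lesion vector, and `shifted_cohort_spec()` moves 0.3 of one subtype's
  mass between two regions (default HER2, cerebellum → putamen) as a
  strong-effect alternative.
- **Geometry.** Lesion centers are drawn uniformly over the sampled
  region's voxels (continuous within-voxel offset) with 2-mm Gaussian
  jitter that is discarded when it would leave the region; radii are
  uniform on 2–8 mm, spanning small punctate to large metastases.
  All draws flow from one seeded generator.

The toy atlas is eleven disjoint 40-mm boxes on a 144³ 1-mm grid. Real
anatomy is not modelled — no gray–white junction, no vascular watershed, no
lobe shapes — which is acceptable because every downstream computation is
geometry-agnostic: it sees only labelled voxel sets. Passing round-trip
tests therefore demonstrate the correctness of the mapping chain, not that
real registration or segmentation error is negligible. Likewise the
generator draws lesions independently given the subtype, so it cannot probe
within-patient clustering; the contingency test pools lesions and is
insensitive to this, but per-patient analyses would need a richer model.

## Validation strategy and problem sizes

The imaging stages have no published numeric outputs, so they are validated
by construction: sphere voxel counts against a brute-force triple-loop
oracle; COG translation-equivariance over 200 random components;
frequency-map additivity and permutation-invariance; residuals against an
exact rational-arithmetic oracle; Kruskal-Wallis against a direct rank
computation; and a simulate → render → map round trip requiring ≥ 95%
region recovery for lesions whose true center is at least 10 mm inside its
region box (with ≤ 8-mm radii and a 10-mm nearest-label search, interior
lesions can only be lost to merging with a neighbour, so recovery is near
total; boundary lesions may legitimately flip and are excluded).

Monte-Carlo calibration uses 2000 replicates: under the shared-preference
null the analytic test's rejection rate at α = 0.05 should lie in
[0.03, 0.07] (binomial noise band), and against the 0.3-mass shift at
study-sized groups the power exceeds 0.9. Round-trip checks render three
study-sized cohorts (~900 lesions). These sizes keep the full suite under a
minute per heavy check while leaving the binomial confidence intervals
tight enough to detect miscalibration.

## Known limitations

- Registration is consumed, never estimated; garbage affines give garbage
  standard-space coordinates without warning beyond field-of-view checks.
- The adjusted-residual normal approximation degrades in near-empty cells
  (see the pineal-body discussion above).
- The 437-row example records file is a synthetic expansion; only its
  region × subtype margins are real.
- Anisotropic grids are supported by the geometry code (distances use the
  affine), but all shipped fixtures and defaults are 1-mm isotropic.
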