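# Methods

## Scope and data model

The pipeline starts *after* tractography, model fitting and spatial
normalisation: its inputs are per-subject 3-D volumes on one common voxel
grid — a binary dentate-nucleus (DN) mask per hemisphere, one
streamline-count (track-density) volume per connectivity target, and seven
scalar diffusion-metric volumes (FA, MD, AD, RD from the diffusion tensor;
MK, AK, RK from the kurtosis model).  Grids are compared by shape and by
affine entries to within 1e-4 mm; no resampling or registration is
performed, and inputs on different grids are rejected rather than
interpolated.  Voxel indexing is 0-based; world coordinates come from the
NIfTI affine, and "medial"/"lateral" are defined by distance from the
mid-sagittal plane |world x|, which requires the input affine to place
that plane at x = 0 (a documented input contract).  Label 0 always means
background or unassigned: the winner-takes-all rule needs an explicit
no-winner value for voxels with all-zero membership vectors, and the modal
atlas needs a no-vote value.

## Connectivity-based parcellation

For each DN voxel the membership vector stacks the raw streamline counts
of the T targets at that voxel.  "Connection strength" is the raw count,
not a density- or volume-normalised quantity; winner-takes-all is
invariant to any common positive rescaling, so normalisation would only
matter for the retention thresholds, which are defined on raw counts.
Ties are broken toward the lowest target index by default (deterministic
and order-stable); an alternative policy marks tied voxels unassigned.
Volume fractions are percentages of *all* DN voxels, so the per-target
fractions plus the unassigned fraction sum to exactly 100.

Retention uses strict inequalities (a target must have *more than* the
streamline threshold and *more than* the volume threshold).  The filter is
exposed at both the per-subject and the group-mean level, since summaries
can be computed from either.

## Microstructure-based parcellation

The feature matrix (DN voxels × 7 metrics) is processed per subject:

1. **Max-normalisation** — each feature divided by its own maximum over
   that subject's DN voxels, mapping every column into (0, 1].  This runs
   before outlier replacement by default; the order is a config flag
   (`normalize_first`) because either order is defensible and the two
   differ only when outliers move a column maximum.
2. **IQR outlier replacement** — values outside [Q1 − 1.5·IQR,
   Q3 + 1.5·IQR] are replaced by the column median.  Quantiles use linear
   interpolation (NumPy's default, R type 7) and the median is computed on
   the pre-replacement column, which makes the operation idempotent.
3. **Fuzzy c-means** — c = 3 clusters, fuzziness m = 2, squared Euclidean
   distances.  Initial memberships are random row-stochastic matrices; 5
   restarts are run and the lowest final objective kept, which makes the
   result stable at this problem size (~900 voxels per nucleus).
   Iterations stop when the objective changes by less than 1e-6 or after
   300 iterations.  The alternating updates make the recorded objective
   sequence non-increasing (each half-step is an exact minimiser given the
   other block); a voxel coinciding exactly with a centroid receives full
   membership there, split equally if several centroids coincide.
4. **Hardening and reduction** — voxels take their most probable cluster
   (ties to the lowest index).  With three nonempty clusters, the pair
   with the closest feature-space centroids is merged (a single
   agglomerative step); the surviving cluster whose voxel centroid lies
   nearer the mid-sagittal plane is named *medial* (label 2), the other
   *lateral* (label 1).  The merge rule is this package's design choice
   for reducing three clusters to a reproducible two-cluster atlas; other
   bottom-up rules would be possible, and the hardened three-cluster
   labels remain available upstream of the reduction.

## Group atlases and comparison

The modal atlas assigns each voxel the most frequent nonzero label across
subjects; an unassigned voxel casts no vote, ties go to the lowest label,
and an optional `min_support` fraction (default 0) zeroes voxels whose
winning label is carried by too few subjects — made explicit here because
visual inspection is not reproducible.  Per-label probability maps divide
by the total subject count, so per-voxel sums are ≤ 1 with equality
exactly where every subject labels the voxel; wherever a unique maximiser
exists, the modal atlas equals the argmax of the probability maps.

Dice similarity between two parcels is 2|A∩B|/(|A|+|B|); two empty
parcels score 0 (absence of both is not evidence of agreement), and the
matrix is computed over nonzero labels only.

## Nonparametric statistics

All tests are two-sided at α = 0.05 with no multiple-testing correction —
a deliberate mirroring of common practice in small normative studies, and
a caveat for any user interpreting many p values at once.  Wilcoxon
signed-rank drops zero differences and uses the exact distribution for up
to 25 remaining pairs (conditional on the observed ranks), else a normal
approximation with tie correction; an all-zero difference vector returns
p = 1 with a warning.  The Friedman statistic uses mid-ranks and the
standard tie-correction factor, referred to χ²(k−1); a table whose rows
are all constant carries no ranking information and returns (0, 1).
Mann-Whitney U is exact for combined n ≤ 25 without ties, else normally
approximated with tie correction.  Calibration under the null
(2,000 simulated datasets per test at the sample sizes used in the
acceptance script: 25 pairs, 30×3 tables, 12 + 12 groups) lands the
empirical type-I error within 0.05 ± 0.02 for all three tests.

## Synthetic cohort

The generator emulates the *statistical* structure of the real inputs,
not their anatomy:

* **Geometry** — each DN is an ellipsoid (default semi-axes 9 × 6 × 8 mm
  on a 1.25 mm isotropic grid, ≈ 900 voxels, mirrored at ±13 mm from the
  mid-sagittal plane), matching realistic nucleus dimensions.  The
  connectivity truth is a partition into contiguous bands of constant
  |world x| (medial → lateral in target order) whose voxel-count fractions
  follow the requested volume fractions to within one voxel per boundary;
  the microstructure truth is a 55/45 lateral/medial split.  Banded
  geometry mirrors the medial-to-lateral ordering of the real
  parcellations while keeping the truth analytically checkable.
* **Counts** — streamline counts are event counts, so they are Poisson: a
  voxel of parcel p emits at rate λ_p(1−leakage) on its own target and
  λ_p·leakage/(T−1) on each other target, with λ_p = (per-nucleus parcel
  total)/(parcel voxels).  Default parcel totals and volume fractions are
  the reported left-DN across-subject means (cerebellar: 18.9k, 38k,
  9.2k, 2.7k, 2k, 11.8k streamlines at 28.9/39.5/8.0/3.0/4.2/16.4% of DN
  volume; thalamic: 330/390/50/60/1/30), giving per-voxel rates of
  roughly 50–130 for cerebellar targets.  Default leakage is 0.1.  Counts
  for the two hemispheres are drawn separately because the totals are
  per-nucleus quantities.  The thalamic count maps share the planted
  band geometry and differ only in their per-target totals; they exercise
  the low-count regime rather than plant a second independent topography.
* **Metrics** — Gaussian around per-cluster means, truncated at zero
  (all seven metrics are nonnegative).  Default means sit at plausible
  DN values (e.g. FA 0.28 vs 0.32, MD 0.81 vs 0.75 ×10⁻³ mm²/s, MK 1.16
  vs 1.21) with per-metric separations of 4 sd, i.e. clearly but not
  trivially separated clusters.
* **Subject variability** — i.i.d. per-voxel label noise (default 0.2):
  a subject's true label is replaced by a uniformly random *other* label
  before counts and metrics are drawn.  Spatial warps are deliberately
  not modelled, since registration is outside the pipeline's scope.
* **Reproducibility** — the entire cohort derives from a single seed and
  is bit-reproducible.

What passing tests on this phantom do and do not show: they demonstrate
that the implementation recovers a planted topography under Poisson count
noise, inter-target leakage, metric noise and inter-subject label noise at
the reported effect sizes — they do not validate tractography, model
fitting, registration, or behaviour under spatially correlated artifacts,
partial-volume effects, or misregistration, none of which the generator
models.

## Problem sizes and numerical choices

Default analyses run one nucleus of ≈ 900 voxels, 6 targets, 7 metrics
and 25 subjects; the acceptance script uses 10 noise realisations for the
clustering chain, 20 random instances per oracle-equivalence check, and
2,000 null simulations per statistical test.  Grid equality tolerance is
1e-4 mm on affine entries, membership row-sums are enforced to 1e-9, and
FCM convergence is 1e-6 on the objective.  Degenerate inputs fail loudly:
singular affines, non-integer label data, empty masks, all-zero feature
columns, fewer voxels than clusters, fewer than two nonempty clusters at
reduction.

## Known limitations

* The 3→2 cluster reduction is a closest-centroid merge; it is one
  reasonable instance of a bottom-up hierarchical rule, not the only one.
* Retention thresholds are taken as given; no sensitivity analysis is
  built in.
* The synthetic cohort shares one DN mask across subjects, so
  partial-coverage effects at group level (voxels inside only some
  subjects' masks) are exercised only via label noise and `min_support`.
* No multiple-testing correction is applied by the statistics module.
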