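# Methods

This note documents the models, conventions and numerical choices behind
`koosgrade`, and what the synthetic validation does and does not show.

## Canonical grid

All geometry is computed on a canonical grid: RAS orientation (grid axis
0 → subject Right, 1 → Anterior, 2 → Superior) and isotropic voxels,
default 0.8 mm, via nearest-neighbour resampling. Reorientation is a pure
axis permutation/flip decoded from the NIfTI affine (s-form preferred when
both forms are present) — voxel values and physical positions are
untouched, so the operation is idempotent and distance-preserving. The
resampled grid is anchored at the input origin with
`ceil(extent / target)` voxels per axis; exact-midpoint ties in the
nearest-neighbour lookup resolve toward the lower input index, making
resampling deterministic. Both branches of the classifier consume the
same canonical grid.

## Geometric predictors

- **Volume** is exactly `N_c × V_v` with `V_v` the product of spacings.
- **Shortest distance** is the minimum over voxel-center pairs, computed
  with a k-d tree over physical coordinates; the arithmetic per pair is
  the same square-root-of-squared-differences as a brute-force scan, so
  the result equals the all-pairs oracle exactly (asserted, not
  approximately, in the tests). Voxel-center distances mean physically
  touching structures measure one voxel spacing (0.8 mm), never 0;
  classifier thresholds learned on this scale are self-consistent.
- **Contact area** follows three literal steps: collect tumor voxels with
  a face (6-connected) neighbour of the structure — face adjacency is
  what defines a shared surface, corner adjacency contributes no area —
  then marching-cubes the binary shell at iso-level 0.5 with physical
  spacing, then sum triangle areas. The closed mesh around a one-voxel
  shell measures roughly twice the geometric interface plus rim terms; the
  factor is constant and harmless to tree-based classifiers, and the
  face-count oracle in the tests documents the relationship.
- **Missing structures** (e.g. contralateral anatomy outside a restricted
  field of view) yield a configurable sentinel distance, default 100 mm —
  large relative to any real intracranial gap — plus a per-case warning;
  the batch continues rather than aborting.

## Tumor side and ipsilateral/contralateral labels

The side is the sign of the difference between two sagittal-axis
projection means: the tumor mask's (indicator-weighted) and the MR
image's (intensity-weighted, negatives clamped to zero so signed intensity
conventions cannot flip the comparison). Under RAS a larger sagittal
coordinate is subject right. Exact equality of the means — a
measure-zero event — resolves to left, deterministically. Detection is
invariant to uniform intensity rescaling; a `--side` override exists for
restricted-FOV images. Hemisphere renaming to ipsi/contra is pure scheme
metadata; voxels are untouched.

## Classifiers

**Random Forest.** scikit-learn's implementation with 100,000 trees,
maximum depth 5, minimum 2 samples per leaf, defaults otherwise. Tests,
examples and the acceptance script use 500 trees: beyond a few hundred
trees predictions on desk-scale cohorts are unchanged, and the full count
only slows the suite. Optional class weighting (inverse frequency) is
exposed but off by default. The criterion and feature-subsampling
defaults are whatever the installed scikit-learn pins — a reproducibility
caveat across library versions, mitigated by recording the configuration
in the model artifact.

**Volume baseline.** Candidate cutoffs are midpoints between consecutive
distinct sorted training volumes plus two finite boundary sentinels (the
minimum volume itself, so the grade-I band can be empty, and max + 1, so
the grade-IV band can). All ordered triples are scored by training
weighted F1 of `grade(v) = 1 + #{t ≤ v}` (boundary rule `cut ≤ v`);
scoring is vectorised per top cut via cumulative per-grade pass counts,
and ties resolve to the first triple in enumeration order. An
independent plain-loop search cross-checks the optimum in the tests.

**Backward feature elimination.** A seeded stratified split holds out
20 % for validation; each iteration fits a forest, records validation
accuracy, and drops the single lowest-importance predictor down to one.
The earliest (largest) predictor set achieving the maximal recorded
accuracy wins — dropping one predictor per iteration keeps the importance
ranking fresh.

**Ensemble.** Plurality over the vote panel; grades tied for most votes
are ranked by caster votes (the Random-Forest votes are the casters); a
residual tie resolves to the lowest ordinal grade — a deliberate,
documented cascade that favours the less severe grade when the evidence
is perfectly balanced. External network votes enter only as per-case CSV
files; no neural model is trained or shipped.

## Evaluation statistics

- MA-MAE restricts the outer average to classes present in the ground
  truth (the per-class normalisation forbids empty classes); with
  balanced classes it equals the plain mean absolute error.
- Per-class F1 with zero precision + recall is 0; weights are true-class
  supports.
- The corrected resampled paired t-test uses the unbiased (k − 1
  denominator) variance and k − 1 degrees of freedom. The test/train
  ratio for k-fold CV defaults to `(1/k)/(1 − 1/k)` (0.25 at k = 5); the
  inverted train/test reading (4.0 at k = 5) appears in parts of the
  literature, so both conventions are supported explicitly rather than
  silently picking one. All-zero differences (a method against itself)
  return t = 0, p = 1 rather than an error, since the comparison is
  well-defined even though the variance degenerates.
- Stratified k-fold shuffles each grade with the seed and deals cases
  round-robin with a *single position carried across grades*, so per-grade
  counts and total fold sizes both differ by at most one — 308 cases over
  5 folds always yields a largest fold of 62.
- Quadratic (Fleiss–Cohen) kappa weights are `1 − (i−j)²/(k−1)²`; on this
  scale a two-grade disagreement costs 4× a one-grade one and a
  three-grade disagreement 9×.

## Phantom generator

Primitives (spheres/ellipsoids, half-open boxes, slabs) are digitized by
voxel-center containment on an 80³ grid at 0.8 mm (63.2 mm cube); the
tumor overwrites any structure it overlaps; overlapping non-tumor
primitives are an error. The anatomy is mirror-symmetric about the
mid-sagittal plane: brainstem and pons at the midline, three vermal boxes
posterior, a cerebellum box per side; the internal auditory "meatus" is a
plane 16 mm lateral of the midline. Closed-form truths (ellipsoid
volume, sphere–box nearest-point gaps) are recorded per case.

The planted feature→grade rule mirrors Koos logic at desk scale:
grade IV if the brainstem distance ≤ 2 mm *and* volume ≥ 2500 mm³;
grade III if brainstem distance ≤ 2 mm; grade II if the ipsilateral
cerebellum is contacted (or within 2 mm); else grade I. The 2 mm touch
threshold sits above the 0.8 mm one-voxel distance of digitized touching
surfaces and above the voxel diagonal (1.39 mm); the 2500 mm³ cutoff sits
in the gap between the largest grade-III sphere (r = 8 mm, 2145 mm³) and
the smallest grade-IV sphere (r = 9 mm, 3054 mm³). Tumor geometry is
sampled per grade with explicit margins (grade II stays ≥ 3 mm clear of
the brainstem, grade I > 2 mm clear of the cerebellum), so the rule
applied to *extracted* features reproduces the planted grade on all
zero-noise cases.

Cohort defaults are 200-case scale with an equal grade mix and zero label
noise; an imbalanced mix emulating the clinical scarcity of grade I and a
degradation profile in which hrT2-tagged masks suffer more boundary
jitter/dropout than ceT1 (and the combined modality least) are available
but off by default. Degradation erodes/dilates each structure by up to
the jitter amount (dilation only into background) and drops boundary
voxels with the given probability.

**What the phantoms do not show.** They share none of the hard parts of
clinical data: no MR intensity ambiguity, no segmentation errors beyond
the synthetic jitter model, no anatomical variability, no borderline
III-vs-IV compression judgements, and a grade rule that is exactly
representable by the extracted features. Passing tests therefore
validate the *implementation* — geometry, classifiers, statistics — not
clinical accuracy; the near-perfect phantom CV scores are a property of
the noiseless planted rule, not a clinical claim.

## Problem sizes and numerical choices

Tests and the acceptance script use: a 200-case zero-noise cohort (seed
fixed), 500-tree forests, 5-fold CV, 100 random fixtures for the exact
distance oracle, 5000 cases for the kappa null, and 20 seeded runs for
the feature-elimination recovery check. Thresholds quoted above (3 %
sphere-volume digitization error at r = 8 mm / 0.8 mm spacing, one voxel
diagonal for distance truths, ±10 % on the contact-area scaling) are
digitization bounds, not fitted tolerances.

## Known limitations

- Single unilateral tumors only; bilateral (NF2) cases are out of scope.
- The contact area carries the ≈2× closed-mesh factor by construction.
- Distances are voxel-center based and cannot distinguish touching from
  one-voxel-apart at native resolution.
- The Random Forest's unpinned scikit-learn defaults may drift across
  versions; the artifact records its configuration.
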