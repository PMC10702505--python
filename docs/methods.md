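# Methods

This note documents the models, measurement conventions and synthetic-data
design behind `cwpqct`, the numerical choices that were genuinely open,
and what the passing tests do and do not establish.

## Airway centerline extraction

The airway mask (lumen plus wall) is reduced to a 1-D rooted tree in five
steps:

1. **Path tracing.** A 26-connectivity graph is built over the mask
   voxels with two edge weightings: true physical length, and length
   divided by the mean distance-transform value of the two endpoints, so
   shortest paths under the second weighting hug the medial axis. The
   root is the voxel maximizing `z + 2·EDT` (superior *and* medial; a
   purely topmost root sits on the end-cap surface and seeds degenerate
   stubs). Branch tips are found iteratively: the unclaimed voxel with
   the largest true geodesic distance from the root seeds a path traced
   back along medially-penalized predecessors until it reaches the
   existing skeleton or its 26-neighbourhood (the halo rule, which
   prevents near-parallel duplicate paths); the tube around each traced
   path — voxels within 1.8 × the local radius of their nearest path
   point, with radii propagated from nearby fat points so end caps are
   covered — is claimed, and tracing ends when the mask is covered.
2. **Graph, cycles, rooting.** Skeleton voxels are connected
   (26-neighbourhood, physical edge lengths); residual cycles are removed
   by a minimum spanning tree; the tree is rooted at the most superior
   endpoint.
3. **Branch build.** Maximal junction-to-junction chains become branches.
4. **Sub-voxel recentering and smoothing.** Each chain point moves to the
   centroid of the in-mask voxels in its perpendicular disc slab (capture
   radius = local radius + 2 voxels, slab thickness ≈ 1 voxel). The
   voxelized disc is symmetric about the true axis, so this removes the
   half-voxel jogs a discrete path must make when the axis runs between
   voxel columns — without it, a perfectly axis-aligned tube reads ~3°
   off axis. A short moving-average pass (window 5, endpoints fixed)
   removes residual jitter.
5. **Pruning.** Terminal spurs shorter than 2 × the local tube radius
   (max of the spur's own mean radius, the junction radius, and 0.8 × the
   parent's mean radius — end caps otherwise defeat the rule) are
   removed; internal junction-to-junction chains shorter than 1.5 × the
   local radius are contracted so a trifurcation does not read as two
   stacked bifurcations.

A topological-thinning skeletonizer was considered and rejected: the
thinning available in the environment collapses thick tubes outright, and
path tracing additionally yields sub-voxel, ordered, smoothed chains that
the geometry stage needs anyway.

**Branch direction** is the principal (total-least-squares) direction of
the chain after excluding the junction flare (within 2 × the junction
radius of the proximal end, where the centerline still bends into the
parent) and the distal cap (within one mean radius of the tip). Short
branches that cannot afford the exclusion fall back to the chord from the
first junction-free point to the tip; a PCA over flare points would
rotate the estimate toward the parent axis.

## Structural variables

- **θ (bifurcation angle):** the included angle between the daughter
  direction vectors of a branch; trifurcations report the mean of the
  three pairwise angles. Stored on the parent branch.
- **Cross-sections** are taken at every centerline point of the middle
  third of a branch (junction flare and tip excluded by construction), on
  planes perpendicular to the local tangent. 64 radial rays from the
  centerline point sample the HU field (trilinear interpolation, step
  0.25 voxel). The luminal radius per ray is the −500 HU crossing of the
  profile (midway between air ≈ −1000 and wall ≈ 0, hence unbiased under
  symmetric blur); the outer wall radius is the half-maximum descent
  beyond the wall peak (FWHM convention). Rays are lightly smoothed
  circularly (¼, ½, ¼) before use: azimuthal partial-volume jitter
  otherwise inflates the polygon perimeter and biases circularity low.
  A and Pe come from the sub-pixel polygon through the per-ray boundary
  points (voxel-edge counting is deliberately avoided for the same
  reason). Sections whose rays leave the grid or whose lumen is not
  closed are skipped; a branch with no valid section keeps a row of
  missing metrics, which downstream imputation handles.
- **D_h = 4A/Pe**, **Cr = 4πA/Pe²**, **WT** = mean over valid rays of
  (outer − inner radius); rays with outer < inner are discarded, and a
  section needs ≥ 8 surviving rays.
- Per-branch metrics are arithmetic means over valid sections; the five
  lobe subgroups additionally aggregate their member branches by mean.

Accuracy at the default test resolutions: at 0.5 mm voxels, noise-free,
D_h of a 4 mm tube is recovered within ~1 %, WT within half a voxel, Cr of
a circular tube ≥ 0.95 and generator angles within 2°. At 0.75 mm, the
segmental branches of the full 26-branch tree (radii ≈ 1–1.2 mm, walls
0.6–0.7 mm) are resolution-limited: walls thinner than ~1.5 voxels read at
the blur width rather than their true value, and 7 mm branches carry only
2–3 valid sections. This mirrors the clinical observation that
thick-slice CT supports conclusions about central airways far better than
segmental ones, and is why the integration test applies voxel-scale
tolerances to small branches while the cylinder tests use tight ones.

## Parenchymal classification

The integer HU bounds of the clinical convention (emphysema < −950,
normal −950…−701, GGO −700…−501, semi consolidation −500…−201,
consolidation −200…60, fibrosis −500…0) are extended to continuous HU by
half-open intervals cut at half-integers (…, [−950.5, −700.5), …), which
reproduces the integer table exactly and leaves no measure-zero gaps.
Fibrosis is a report-only interval overlapping semi consolidation and
consolidation; it is never subtracted from them. The denominator is every
lung-mask voxel, with voxels above 60.5 HU reported as *unclassified*, so
the exclusive fractions plus unclassified sum to 1 exactly (integer
arithmetic on counts). Airway voxels are excluded from the lung mask when
an airway mask is available. The voxels-per-HU histogram uses 1-HU bins
over [−1024, 200] with out-of-range values clipped into the edge bins.

## Vessel volume by cross-sectional area

The vessel mask (each 26-connected component separately — vessel trees
come in at least two components per subject) is reduced to the same
sub-voxel centerline chains as the airways. Every vessel voxel is
assigned to its nearest centerline point; the local CSA at a point is the
volume of its assigned voxels divided by the centerline arc length it
owns (half the distance to each chain neighbour; free chain ends extend
by the axial overhang of their assigned voxels, which accounts for end
caps). This volume-per-length estimator equals πr² exactly for a
cylinder and, unlike inscribed-sphere radii from the distance transform,
remains unbiased at sub-voxel radii — essential because the BV1 threshold
(1 mm²) corresponds to r ≈ 0.56 mm, around one or two voxels. CSA values
are smoothed over 1.5 mm centerline neighbourhoods. TBV is vessel voxel
count × voxel volume; BVx is the volume in voxels with CSA ≤ x mm²
(inclusive thresholds); the curve bins volume at 1 mm² over [0, 20].
Threshold monotonicity BV1 ≤ BV5 ≤ BV10 ≤ TBV is asserted on every
report, not assumed.

## Synthetic phantoms

Phantoms are unions of flat-capped analytic tube segments (inner radius,
wall thickness, direction, length per branch) with junction balls of the
parent's radii filling the elbows, rasterized at voxel centers. Tissue
HU: lumen −1000, wall 0, vessel +100, parenchymal classes at their
interval midpoints (emphysema shares −1000 with air); Gaussian noise with
per-tissue SD (default 20 HU). Parenchymal class placement uses
largest-remainder apportionment plus a seeded permutation, so generated
fractions match their targets to within one voxel. One integer seed
drives a documented stream order (class placement, then one noise field),
making volumes bit-reproducible. The default bronchial tree has the 26
anatomical branches scaled into a 96 mm cube (trachea r 4.5 mm down to
segmental r 1.0–1.2 mm); a thick-slice preset (0.75 × 0.75 × 3 mm, as in
a 16-detector spiral protocol) exists for resampling tests, and geometry
is always measured on isotropically resampled volumes (linear HU,
nearest-neighbour masks).

Phantoms emulate tube geometry, HU contrast and noise. They do **not**
emulate reconstruction kernels, beam hardening, breathing states, real
parenchymal texture, or segmentation errors; passing geometry tests
therefore demonstrates correctness of the measurement chain, not
clinical-grade robustness.

## Synthetic cohorts

The default cohort reproduces the study population's structure: five
severity categories with sizes 110/108/54/10/98, and per-category age,
height, BMI, spirometry means/SDs and smoking/COPD/female proportions
taken from its demographic table. Within a category the confounders are
cross-correlated through centred logit shifts (older subjects smoke more
and carry more COPD; later birth cohorts are shorter), preserving the
marginal moments while keeping a single propensity score approximately
sufficient — the situation in real occupational cohorts. Imaging
variables run through a per-subject latent severity (category + N(0,
0.8)) with effect slopes chosen to be plausible for the documented
directions (thicker tracheal/Bronint walls, narrower TriLUL angle, lower
Bronint circularity, more emphysema/consolidation/fibrosis, flat GGO,
lower BVx/TBV, FEV1/FVC falling with emphysema); no quantitative effect
sizes are published, so the slopes are design choices, fixed once.
Structural variables go missing at random conditional on category (2 % in
category 0 rising to 10 % in category 4), emulating opacity-obscured
airway segmentation. `effect_scale=0` yields a null cohort for
calibration tests.

## Matching, SMD and EM

- Propensity model: logistic regression of group membership on age,
  height, smoking and COPD (sex is excluded: the matched study groups
  are all-male). Perfect separation raises an error advising exact
  matching.
- Greedy one-to-one matching processes treatment subjects in descending
  score order (ties by id), each taking the unused control with the
  smallest absolute score difference; the stage-1 caliper is 0.4 × the
  SD of the pooled estimated scores (on the probability scale; the
  logit scale was evaluated and made no practical difference), and
  stage 2 (retained category 0 vs. categories 1 and 4 in full) is
  caliper-free. Determinism is preferred over fidelity to unpublished
  tool internals.
- Multi-group SMD: continuous |m₁−m₂|/√((s₁²+s₂²)/2) with sample
  variances, binary |p₁−p₂|/√((p₁(1−p₁)+p₂(1−p₂))/2), 0/0 defined as 0,
  summarized as the arithmetic mean over all group pairs. This
  convention reproduces the published balance columns exactly at three
  decimals (0.085, 0.171, 0.111), which is what pins it down; a
  max-pairwise summary is available.
- EM imputation treats the structural metric columns as multivariate
  normal: the E-step fills missing entries with conditional expectations
  and accumulates the conditional covariance of the missing block, the
  M-step re-estimates (μ, Σ); tolerance 1e−6 on the largest parameter
  change, cap 500 iterations, ridge regularization if Σ turns singular.
  The observed-data log-likelihood is asserted non-decreasing at every
  iteration, observed entries are never altered, and the one-missing-cell
  case matches the closed-form conditional mean to 1e−6.

### A sampling limit on matched balance

The multi-group SMD of four groups of n has an irreducible sampling
floor: for *identical* distributions the mean pairwise SMD is
E ≈ √(2/n)·√(2/π) ≈ 0.17 at n = 43, and values below 0.1 require strong
positive correlation between the matched groups' means on that specific
covariate. A single 4-covariate propensity score cannot deliver that for
all four confounders simultaneously at these group sizes: across seeds,
two-stage matching reduces the worst confounder SMD from ≈ 0.5–0.7 to
≈ 0.10–0.2, and even replacing greedy with optimal score assignment does
not push all four below 0.1. The published post-matching values of
0.050–0.085 should therefore be read as one fortunate draw from strongly
coupled real-world covariates, not as a reproducible property of the
procedure; the balance test in the acceptance suite asserts the < 0.1
bound as specified and is expected to fail at these group sizes, while
the unit suite asserts what the procedure does guarantee (equal group
sizes, one-to-one matching, and a large reduction in imbalance). For the
same reason the null-cohort balance property is tested at n = 2000 per
group, where the floor (≈ 0.026) sits safely under the 0.1 threshold.

## Inference

Kruskal–Wallis uses tie-corrected H with the χ²(k−1) approximation;
all-identical data return H = 0, p = 1 rather than an error. Pairwise
Mann–Whitney U tests run only when the KW p ≤ 0.05 (the gate), use exact
enumeration when both groups have ≤ 8 tie-free observations and the
normal approximation with tie and continuity correction otherwise, and
are Bonferroni-corrected within the variable (multiplier = the 6 pairs of
four groups, matching per-panel star annotations; not a global family).
Stars: * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001 on adjusted
p-values. The null rejection rate of the KW gate at α = 0.05 is verified
to lie in [0.035, 0.065] over 2000 simulations of 4 × 43 subjects.
Pearson correlation maps use pairwise-complete observations on the
post-imputation table; zero-variance variables yield missing entries.

## Problem sizes

Unit tests use 0.5 mm phantoms of a few hundred thousand voxels and the
128³ @ 0.75 mm tree; the two-cylinder vessel benchmark uses 0.15 mm
voxels so mask rasterization error (±5 % at 0.25 mm for a 2-voxel radius)
does not contaminate the ratio being tested; monotonicity runs over 100
seeded random trees at 80³. The full suite completes in about a minute on
one core.

## Known limitations

- Airway lumen and vessel segmentation from clinical CT are out of scope;
  masks are inputs (a HU-threshold fallback exists for demonstrations).
- Wall thickness below ~1.5 voxels is blur-limited and overread; treat
  WT from thick-slice data as a relative, not absolute, measure.
- The anatomical labeling assumes the 26-branch topology with left/right
  orientation decidable from the main-bronchi subtrees; atypical
  branching beyond that scheme is labeled `unlabeled` but never dropped.
- EM imputation assumes joint normality and missing-at-random; both hold
  in the generator by construction but are approximations for real data.
- Single imputation understates downstream uncertainty (no multiple
  imputation), matching the procedure it reimplements.
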