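# Methods

This note records the models, parameter choices and numerical decisions
behind `orchard-qsm`, and what the synthetic test bed does and does not show
about real terrestrial-laser-scanner (TLS) data.

## Input model and units

All computation is metric (meters, z-up); traits are converted at the edge to
the units practitioners use (cm for height, mm for diameters, degrees for
angles). A tree is assumed to be an isolated, registered, single-tree cloud —
row-level tree instance segmentation and multi-scan registration are upstream
of this package.

## Structure-aware downsampling

The order-k Hilbert curve (k = 7 by default, a 128³ grid) is computed with the
bit-transpose Gray-code formulation; encode/decode are exact inverses and
consecutive curve indices are face-adjacent cells, which is the locality
property that makes curve cells behave like spatial bins. Each occupied bin
contributes `N_h = max(1, ⌊N_S/#Bins⌋)` points drawn uniformly without
replacement from a seeded generator; leftover budget is redistributed one
point at a time to the largest bins (ties to the smaller bin id). Because
every occupied bin keeps at least one point, thin, sparsely sampled branches
survive aggressive downsampling — the mechanism, not the sampling rate, is
what preserves topology. `N_S` defaults to 50,000 for real scans; the
synthetic suite budgets 10,000 (its trees carry 15–50 k points, so a larger
budget would make downsampling a no-op).

## Laplacian contraction

The contraction solves, per iteration, the stacked least-squares system
`[W_L·L; W_H·I] X' = [0; W_H·X]` where `L` is the row-normalized Laplacian of
the symmetrized k-NN graph (k = 8). Two choices matter:

- **The neighborhood graph is built once, from the input cloud, and kept
  fixed.** Rebuilding it from contracted positions freezes the flow: points
  clump along filaments, their nearest neighbors become the clump, and the
  Laplacian pull vanishes before the cross-section has collapsed.
- **Attraction weights grow as the reciprocal of the local shrink ratio**
  (mean k-NN distance now vs. initially, floored at 0.1), anchoring regions
  that have already collapsed while `W_L` doubles each iteration from 1.
  Ten iterations (final `W_L = 512`) collapse a 25 mm cylinder cross-section
  to under 5 mm of residual radius while shrinking its length by only a few
  percent.

Farthest-point thinning starts from the sample nearest the lowest-z point
(the root anchors the skeleton and makes the greedy sweep deterministic) and
stops when every point lies within ε of a sample; ε = 0.010 × bounding-box
diagonal, which yields roughly 150–300 skeleton vertices on orchard-scale
trees. Connectivity is inherited from k-NN relations between supports, then
3-cycles are removed by repeatedly deleting the triangle's longest edge
(ties: the lexicographically larger vertex pair), which cannot disconnect a
component.

## Thickness from point density

Edge weights use a density proxy for thickness: `m_i` is the reciprocal of
the mean distance from a skeleton vertex to its K nearest original points.
TLS over-samples thick structures (more reflecting surface per unit length),
so density stands in for diameter. K matters more than it looks: a skeleton
vertex sits on the medial axis, so for small K the K-NN distance is simply
the local radius and the proxy *inverts* (thin branches look dense). The
probe must reach beyond one structure radius so that the along-axis sampling
rate, not the radius, dominates; K = 150 does that for trunk radii up to
~35 mm at the point budgets above. The MST stage uses `1/m` (cost low where
returns are dense), the trunk stage uses `+m` (the maximal-weight root path
is pulled through thick wood).

## Segmentation scales

The tube radius R, cluster radius, and extension gate d_ext are resolved per
tree from the skeleton resolution ε rather than fixed in meters:
R = max(0.10, 4.5 ε), DBSCAN eps = max(0.04, 2.0 ε) with min_pts = 1,
d_ext = max(0.08, 3.5 ε). The driver is the *junction shadow*: contraction
pulls the first one-to-three vertex spacings of a branch into the trunk
filament, so branch filaments surface well away from the trunk polyline and
a fixed few-centimeter tube sees nothing. Three consequences are handled
explicitly:

- single-vertex tube clusters borrow their immediate non-trunk tree
  neighbors (within 3 ε) before the line fit, so they carry a heading;
- a cluster is valid when the extension length — the distance from its
  trunk-nearest member to the fitted line's closest approach to the trunk,
  *plus* the residual line-to-trunk gap — is at most d_ext, which rejects
  offshoots whose line never meets the trunk;
- subtrees that hang off the trunk in the MST but were claimed by no cluster
  are rescued as branches: their attachment to the trunk is structural
  evidence the tube test cannot see. Fragments of one branch are merged when
  their trunk-approach points coincide within max(4 cm, ε); genuine
  neighboring branches insert several times that far apart.

The estimated insertion point (midpoint of the fitted line's closest-approach
point and the facing trunk point) is also the anchor prepended to the branch
path before refinement, so diameters and angles are measured from the
junction rather than from wherever the skeleton happens to resurface.

## Cylinder-prior refinement

Each slab center minimizes `Σ|v−xᵢ| + λ·Var(|v−xᵢ|)` by gradient descent
with backtracking from the coordinate-wise median; with λ = 0 this is the
geometric median (checked against a Weiszfeld oracle to 1e-6). λ defaults
to 1. Note the penalty is dimensionful (the variance is in m²): at metric
scale the L1 term dominates unless λ is in the thousands, and large λ trades
occlusion robustness for a measurable bias on sparse slabs, so the default
keeps the median behavior and leaves the equidistance term as a gentle
regularizer.

Cross-section slabs are nominally 1 cm deep but thicken adaptively so each
slab averages at least 24 points: a center optimized over a handful of points
collapses onto them and drags the radius with it (on 10-mm-diameter branches
this was a −2 to −3 mm diameter bias; with the floor it is within ±1 mm).
Thin slabs relative to the radius remain the ideal; sparse surfaces cannot
afford them. Radii are mean in-plane (slab-projected) distances — 3D
distances would inflate with slab depth.

Center sequences pass a per-region seeded RANSAC line filter, then a
semi-global filter over sliding windows of K₁ = 10 consecutive centers
(stride K₁/2); a center is discarded only if every window containing it
calls it an outlier. Inlier tolerance 1 cm. The surviving centers are fitted
per-coordinate with a cubic smoothing spline (GCV-chosen smoothing) against
chord length and resampled at M = ⌈length/2 cm⌉ equal arc-length steps; for
the trunk the exact path endpoints are kept as anchors, because slab centers
sit half a slab depth inside each extremity and the z extent is a trait.
The coarse trunk path itself is first stretched along its end directions to
the farthest cloud point in an 8 cm corridor, recovering the tip and base
that farthest-point sampling stops one resolution short of.

## Traits

- Height: (max z − min z of refined trunk centers)·100 + 60 cm. The offset
  accounts for the rootstock cover removed during field preprocessing and is
  configurable.
- Trunk diameter: bottom 10 cm slice of `P`, largest 3D DBSCAN cluster
  (eps 3 cm, min 5) projected to xy, seeded RANSAC over 5-point direct
  (Fitzgibbon-style) ellipse fits, refit on inliers; diameter = a + b, which
  reduces to the true diameter for a circle.
- Branch diameter: 2 × mean of the first K₃ = 5 refined radii from the trunk
  outward.
- Inclination: the local trunk segment is the set of refined trunk centers
  spanning the branch's z range; its direction comes from seeded RANSAC,
  oriented upward; θ averages the angles of the first K₂ = 5
  consecutive-center branch vectors against it. Angles are 3D; a field
  protractor measures a 2D projection, which is a known protocol mismatch.

## Synthetic orchard and what it shows

The generator models the trunk and branches as tapered generalized cylinders:
trunk height 2.4–3.9 m, base diameter 42–68 mm with 4–10 mm/m taper and up to
5° lean; 6–15 primary branches placed stratified-with-jitter along the trunk,
golden-angle azimuths, inclinations 30–80°, lengths 0.5–1.1 m shrinking with
height (tall-spindle allometry: the leader stays the tallest and longest
axis), diameters tied to length (9–26 mm), gentle downward curvature. Surface
points are area-weighted samples with isotropic Gaussian noise (default
2 mm); per-structure areal density scales linearly with diameter relative to
the trunk (default 5×10⁴ pts/m² on the trunk), emulating the TLS property
that thick structures return more pulses — the very premise the thickness
proxy relies on. Ground truth records per-point structure labels, axis
polylines, insertion points, and the trait values under the field protocols
(trunk diameter at the middle of the measurement slice, branch diameter 5 cm
out from the junction surface, inclination at insertion).

Degradation operators remove angular sectors or axial windows (junction
gaps, occlusion shadows) and add stray uniform returns. On the fixture suite
the pipeline reaches ~95 % branch recall with ~1 % false positives; junction
gaps of 0/12/30 cm collapse recall monotonically (≈0.94/0.45/0.0), and
occluded sectors bias diameters down in 20 of 20 trials — the same failure
directions reported for field data.

What passing these tests does *not* show: performance under registration
ghosting and wind-induced non-rigid deformation, trellis wires and covers,
contact between neighboring trees, secondary-branch clutter, or strongly
anisotropic scanner noise. The suite's surface noise is isotropic and its
occlusions are clean geometric cuts. Field preprocessing (SOR against flying
pixels) is part of the pipeline for real scans but is disabled for the
synthetic suite: the fixtures model already-denoised clouds, and a global
statistical gate on strongly density-contrasted surfaces thins sparse
branches instead of removing outliers.

## Determinism

Every stochastic stage — bin sampling, RANSAC (local, semi-global, ellipse,
trunk vector), spectral clustering, the synthetic generator — draws from a
seed carried in its configuration; MST and triangle-collapse ties break
lexicographically; DBSCAN sees sorted inputs. Two runs with the same cloud,
configuration and seed produce bit-identical trait tables, and repeated runs
give a single branch count. This is the property that separates the pipeline
from reconstruction tools whose outputs vary across runs on the same scan.

## Known limitations

- Primary branches only by default; the trunk-identification recursion can in
  principle descend to higher orders, but traits and tests cover primaries.
- The junction shadow is mitigated, not removed: branch origin estimates are
  accurate to ~2–3 cm, and branches shorter than about three skeleton
  spacings (~25 cm at default resolution) with few dozen points can still be
  missed.
- Diameters of heavily occluded structures are underestimated by design of
  the surface-based radius (no completion or symmetry prior is applied).
- The density-based thickness proxy assumes scan density increases with
  structure size; on clouds where density is uniform (e.g. synthetic data
  sampled at equal areal density), the trunk-vs-branch contrast disappears
  and trunk identification leans on the length term alone.
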