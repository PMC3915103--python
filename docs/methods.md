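# Methods

## Model and procedure

`atlasfuse` segments a subject scan by transferring labels from a
population of expert-labelled atlases. Four stages run per subject:

1. **Pairwise registration.** Every atlas is registered to every other
   atlas and to the subject (directed pairs; the subject is never a moving
   image). Registration is behind a backend contract: all later stages
   consume only displacement fields in the pull-back convention
   `output(x) = moving(x + u(x))`, with `u` in voxel units on the fixed
   grid. The builtin backend is a multi-resolution demons-style
   registrator (Thirion forces on the mean-squared difference, Gaussian
   field regularization each iteration); precomputed fields from any
   external tool can be injected instead, and a pass-through "oracle"
   backend serves ground-truth fields in tests.
2. **Cost graph.** Directed edge *i → j* is scored
   `e_ij = w1·M̂ + w2·Ĥ`, combining the intensity residual after warping
   (`M`, mean squared difference, intensity² units) and the harmonic
   energy of the field (`H`, mean Frobenius norm of the displacement
   Jacobian, dimensionless). The two terms are incommensurate, so each is
   min–max normalized over all graph edges before weighting; this also
   bounds costs in [0, 1], which makes the later voting weight `1 − e`
   well defined. A degenerate term (all edges equal) normalizes to zero
   rather than amplifying noise. The Jacobian is taken of the
   *displacement*, not the full transform, so the identity deformation has
   zero shape cost.
3. **Selection.** Floyd–Warshall shortest paths from each atlas to the
   subject; atlases whose paths share a vertex (subject excluded) are
   merged into one cluster (union-find closure — an atlas always lies on
   its own path, so routing through a neighbour joins its cluster). Each
   cluster contributes one exemplar: the member with the smallest path
   cost to the subject; its voting weight is one minus its *direct* edge
   cost to the subject, clamped to [0, 1]. The clustering depends on the
   subject and is recomputed per subject.
4. **Fusion.** Exemplar label maps are warped to the subject grid with
   nearest-neighbour interpolation and fused per voxel by weighted
   majority vote. Background (label 0) votes like any label; ties go to
   the smallest label value. Only global (per-exemplar) weights are used —
   no per-voxel weighting.

**Assumptions on inputs**: scans are bias-corrected, rigidly aligned to a
common space, skull-stripped, and share one grid. Preprocessing is
deliberately out of scope.

## Path-cost aggregation (a genuinely open choice)

"Shortest path" requires an aggregation of edge costs along a path. With
*additive* cost and approximately metric edges — which is what accurate
registrations produce, since deformation-based costs roughly satisfy the
triangle inequality — the shortest path from any atlas is always its
direct edge: clustering degenerates to singletons and selection becomes
vacuous (every atlas selected). We therefore default to the **bottleneck
(minimax)** aggregation: a path costs its worst edge. An atlas whose
direct edge is worse than a similar neighbour's then routes through that
neighbour, which is exactly the chaining that makes path-sharing a
meaningful cluster signal. Bottleneck costs tie across a chained cluster,
so the exemplar choice breaks ties by (path cost, direct edge cost, node
index). `floyd_warshall(..., path_cost="additive")` retains the additive
variant; all other tie-breaks are by smallest node index, making the whole
pipeline deterministic.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `w1`, `w2` | 0.2, 0.8 | — | weight of intensity vs shape term; shape dominates. `w1 + w2 = 1` enforced at config load |
| builtin `levels` / `iterations` | 3 / (60, 30, 10) | — | coarse-to-fine demons schedule; deterministic, seedless |
| builtin `smooth_sigma` | 1.0 | voxels | Gaussian field regularization per iteration |
| builtin `max_step` | 2.0 | voxels | caps per-iteration update; guards against instability |
| voting weight | `1 − e(exemplar→subject)` | — | clamped to [0, 1]; a weight of exactly 0 is legal and logged |

## Synthetic phantom populations

The generator emulates the structure a multi-atlas study must cope with,
at desk scale (32³ voxels, 1 mm isotropic by default):

* **Base anatomy**: four compact structures — one large thalamus-like
  ellipsoid, one thin ventricle-like sheet (stresses surface metrics), two
  small spheres — embedded in a tissue envelope whose outside is zero
  intensity (the skull-stripped look; this also matches the warper's
  out-of-bounds convention, so borders carry no artificial gradients).
* **Two-tier deformations**: `k_modes` anatomical sub-types, each a flow
  of a smooth random stationary velocity field (scaling-and-squaring
  exponential — invertible by construction, inverse = flow of the negated
  velocity), composed with smaller per-member flows. Defaults: mode scale
  6 voxels, member scale 1.5 voxels (ratio 4), control-grid spacing ≈
  smoothness σ = 4 voxels. Randomness lives on a coarse control grid so
  typical displacements are commensurate with the nominal scale rather
  than the maximum being a rare noise spike. Mode velocities are
  equalized in harmonic energy (mean scale preserved) so the modes are
  *equally* far from the base — the controlled cluster structure the
  selection stage is supposed to detect.
* **Acquisition per scan**: the crisp anatomy is deformed first; each
  scan — subject included — then gets its own residual multiplicative
  bias (amplitude 0.05, a post-correction level), partial-volume Gaussian
  smoothing (σ = 0.8 voxel), and additive Gaussian noise (SD 2 on
  intensities 0–200). Ordering matters: smoothing the shared base before
  warping would leave the mildly-deformed subject systematically sharper
  than the mode-deformed members, an asymmetry no real population has.
* **Subject**: the base anatomy under its own member-scale flow, so it is
  a scan like any other, near the population centre but identical to no
  atlas.

Ground-truth composed fields (and their exact inverses) are returned so an
oracle registration backend can bypass registration entirely; that is how
the selection and fusion stages are validated independently of
registration quality.

**What the phantom does not emulate**: cortical folding, Rician noise,
partial-volume mixtures of more than two tissues, susceptibility or motion
artifacts, pathology. Passing phantom tests shows the selection and
fusion machinery behaves as designed under known geometry; it does not
certify clinical accuracy, which is dominated by registration quality on
real anatomy.

## Numerical choices

* Warping: `scipy.ndimage.map_coordinates`; trilinear for intensities,
  strictly nearest-neighbour for labels (no invented label values);
  out-of-bounds samples are background 0, not clamped.
* Jacobians: central differences in the interior, one-sided at the
  boundary, in voxel units.
* Normalization over finite entries only; `max − min ≤ 1e-9` collapses a
  term to zeros; absent edges stay `inf` (subject outgoing edges are never
  computed — no path leaves the subject).
* Floyd–Warshall uses strict-improvement updates (`< −1e-15`), so among
  equal-cost paths the first found (fewer hops, smaller indices) is kept.
* Surface metrics: 6-connectivity surface voxels, exact Euclidean distance
  transform with anisotropic spacing, voxel-centre to voxel-centre; MAD
  averages the two directed means, Hausdorff takes the exact maximum.
  Empty masks yield NaN distances with a warning (not an exception); Dice
  of two empty masks is 100 (perfect agreement on absence), one empty is 0.
* Degenerate inputs rejected with `ValidationError`: non-integer labels
  (first offending voxel named), 2-component fields, shape mismatches,
  negative edge costs, empty masks where a mask is required.
* Registration caching: fields are keyed by a content hash of the image
  pair plus parameters; re-runs reuse them (bit-identical results).

## Problem sizes used in tests

The test and acceptance workloads use 32³ phantoms with 9 atlases
(3 modes × 3 members), 20 seeds for mode recovery, 10 seeds for fusion
quality, 100 random graphs (≤ 7 nodes) and 50 random vote stacks against
enumeration oracles, and 20 random mask pairs (≤ 16³) against all-pairs
surface-distance oracles. A full pipeline run with the builtin registrator
(81 pairwise registrations) takes well under a minute on one CPU at this
scale.

## Known limitations

* The builtin registrator is a small-deformation demons scheme — adequate
  for phantom-scale flows, not a topology-preserving large-deformation
  method; for real brain MRI, inject fields from a dedicated tool via the
  external backend.
* Global voting weights only; locally adaptive weighting is out of scope.
* Fixed-point field inversion (`invert_field`) requires displacement
  Jacobian norms below 1; the generator therefore derives inverses from
  negated velocities instead.
* No resampling between mismatched grids — inputs must share a grid.
* The shared-vertex cluster rule is one reasonable reading of
  "atlases on the same shortest path"; alternatives (e.g. requiring shared
  *edges*) would fragment clusters more.
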