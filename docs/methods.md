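# Methods

## The barcode extraction

The descriptor operates on the reduced tree whose nodes are the branch
points and leaves (continuation nodes are kept in the data model for path
and section lengths but contracted away here). Each leaf starts a component
with value `v = f(leaf)`; components are resolved bottom-up: a branch point
is processed once all of its children are resolved, at which point all but
the oldest child (largest `v`) die there, each emitting the interval
`(v(child), f(branch point))`, and the survivor's `v` — by construction the
maximum of `f` over the leaves of the subtree — is carried to the parent.
The final interval is `(v(root), f(root))`. Multifurcations are handled
natively: all but the oldest of *k* siblings die. Each reduced node is
enqueued exactly once and sibling resolution uses a per-parent counter, so
the run time is linear in the node count (asserted by a visit-count test).

Numerical choices:

- **Tie-break.** Siblings with equal `v` are interchangeable for the barcode
  (the emitted bars are identical); for determinism the survivor is the
  maximum by `(v, node index)`, i.e. among tied siblings the smaller-index
  ones are killed.
- **Interval orientation.** Intervals are stored as `(birth, death)` without
  sorting the pair; for radial distance births at leaves exceed deaths at
  branch points, so points sit below the diagonal. Orientation carries
  information and is preserved everywhere (diagrams, images, bottleneck).
- **Merge value.** The survivor hands its component maximum `v(c_m)` to the
  parent, satisfying `v(n) = max f over subtree leaves` at every step. This
  is what makes the algorithm agree exactly with the concentric-sphere
  filtration on outgoing trees; handing over the node's own `f`-value
  instead would break both the definition of `v` and that equivalence.
- **Multiset comparisons** in tests use absolute tolerance 1e-9 in filter
  units after lexicographic sorting.

Filter functions: radial distance (Euclidean, from the root), path distance
(sum of edge lengths), branch order (bifurcations passed; the root counts
iff it has ≥ 2 children), and section length (length of the branch ending at
the node). All vanish at the root except section length, which is 0 there
by construction.

The root's SWC soma samples (type 1) are collapsed to one point at the first
soma sample's coordinates, and each soma child starts a separate neurite
tree. This is a convention: multi-point somas have no canonical reduction,
and a one-point root matches the descriptor's model of the soma as a single
base point.

## Sphere-filtration oracle

An independent quadratic implementation sweeps a sphere of decreasing radius
and tracks connected components of the super-level part of the tree with
union-find (elder rule: on a merge the component with the larger birth
survives). It requires every edge to be outgoing (child strictly farther
from the root than its parent) — the regime in which the sweep and the
descriptor provably coincide — and refuses other trees. It exists purely as
a cross-check; tests assert multiset equality with the production algorithm
on hand-built fixtures and on 50 seeded simulated trees that pass the
outgoing screen (roughly a third of control-parameter trees do).

## Distances

**Density profile / barcode distance.** The profile counts, at every point
x, the intervals whose closed span contains x. It is represented exactly as
a piecewise-constant function on the sorted interval endpoints — no
histogram binning, hence no bin-width parameter; open/closed endpoint
conventions are irrelevant to every integral and are fixed (closed) only so
point queries are deterministic. The distance integrates |profile₁ −
profile₂| by a merged-breakpoint sweep, evaluating counts at cell midpoints;
this is exact for step functions. It is a pseudometric (distinct barcodes
can collide) and is *not* stable under many small perturbations — no
stability test is asserted for it. Tests validate it against dense-grid
Riemann quadrature.

**Bottleneck distance.** Binary search over the sorted candidate radii (all
cross pairwise L∞ distances plus all diagonal costs |b−d|/2) with a
bipartite perfect-matching feasibility test per candidate
(`scipy.sparse.csgraph.maximum_bipartite_matching` on the standard
augmented graph where each diagram's points may also match their diagonal
projections and diagonal–diagonal pairs are free). Exact for the diagram
sizes that arise here (tens of points). The test oracle is an exhaustive
enumeration over all partial matchings at n ≤ 3. Empirical stability of the
whole pipeline — coordinate noise of size ε moves the diagram by O(ε) in
bottleneck distance — is verified on 20 seeded trees over ε spanning
1e-3…1e-1, fitting a line to mean shift vs ε (R² > 0.95 required).

## Unweighted persistence images

Each diagram point contributes an isotropic Gaussian of bandwidth σ,
normalized to unit integral over the plane (mass outside the bounds is
truncated), evaluated at pixel centres of an H×W grid over fixed
(birth, death) ranges. No persistence weighting is applied: points on or
near the diagonal contribute fully, which is the point — short components
carry discriminative signal. Defaults: 100×100 grid; bounds the min/max of
the dataset being compared, padded 5% per axis (bounds, resolution and
bandwidth must be shared across a cohort before averaging or
classification, enforced by a grid-compatibility check); bandwidth by
Scott's rule on the pooled coordinates, `n^(-1/6)` × mean per-axis standard
deviation, falling back to 5% of the span for degenerate spreads. Euclidean
distance between image vectors is *not* claimed stable and no such test is
asserted.

## The random-tree generator

The generator is defined by this package (the shape-parameter semantics,
not any particular reference process): starting at the origin with a random
unit direction, every node with remaining depth budget k ≥ 1 bifurcates;
child directions deviate from the parent direction by polar angle
`B_a · (1 + u)`, `u ~ U(−D_r, D_r)`, at opposite azimuths drawn uniformly;
segment lengths are `B_l · (1 + u)`; the first child keeps budget k−1 while
the second gets `k−1 − round(A_b · (k−1))` (so `A_b = 0` gives a full
binary tree with `2^T_d` leaves and `A_b = 1` maximal imbalance with
`T_d + 1` leaves, the structure depending only on `T_d` and `A_b`). Nodes
are placed only at the root, bifurcations and tips, so generated trees are
their own reduced trees. One seeded NumPy generator stream per tree, drawn
in preorder, makes trees bit-reproducible; group members use consecutive
seeds. Defaults are the control configuration `T_d=5, B_l=10, B_a=π/4,
D_r=0.10, A_b=0`.

What the simulator emulates: balanced, radially growing arbors with
controllable depth, scale, splay, noise and imbalance — enough to exercise
every pipeline stage and to pose grouping problems of graded difficulty.
What it does not emulate: tortuous sections (segments are straight, so
`D_r` never accumulates along a branch), branch-diameter taper, pruning,
boundary effects, or any biophysical growth rule. Consequences observed in
the grouping experiments (20 trees/group, 3 groups, leave-one-out
nearest-group rule under the barcode distance, 10 replicates):

- depth, branch-length and asymmetry groups separate essentially perfectly —
  these parameters move the density profile's support or mass directly;
- branch-angle groups (π/8, π/4, π/2) also separate perfectly here, because
  the angle rescales radial reach deterministically at every level;
- randomness groups (5%, 10%, 40%) separate poorly (≈54%): under this
  generator `D_r` changes within-group *spread* far more than the group
  *mean* profile, and the mean-distance assignment rule systematically pulls
  members of diffuse groups toward tighter groups. This is a property of
  the generator's straight-segment design, not of the descriptor; a
  generator in which noise accumulates along tortuous sections would couple
  `D_r` to radial reach and make it far more discriminable.

Passing grouping tests on these cohorts therefore demonstrates the
machinery, not performance on real neurons; real-data cohorts enter through
the SWC pipeline (`classify` CLI or `cohort_images` +
`train_image_classifier`).

## Classification and ranking choices

- Group score = **mean** `dist_bar` to the group's members (robust to
  outliers; min-linkage is the obvious alternative), query excluded by
  identity or index — leave-one-out.
- Ties in group scores and in rankings break lexicographically for
  reproducibility.
- Ward linkage is applied to the precomputed `dist_bar` condensed matrix via
  `scipy.cluster.hierarchy.linkage`. Ward's variance criterion formally
  assumes Euclidean distances; using it on a non-Euclidean pseudometric is a
  pragmatic, widely used device and is treated as such.
- Supervised classifiers are scikit-learn's `DecisionTreeClassifier`
  (unlimited depth) and RBF `SVC`, seeded, on flattened image vectors with a
  stratified train/test split (default 25% held out). Label merging (e.g.
  two subtypes into one superclass) is supported before fitting. No
  hyperparameter tuning is performed.
- Experiment seeds: trial t, group g, member i uses seed
  `base + t·(groups·n) + g·n + i`, keeping all trees distinct within an
  experiment while fully reproducible.

## Problem sizes

Defaults used by the test suite and the acceptance script: 20 trees per
group × 3 groups × 10 replicates per grouping experiment (600 classified
trees each, ~2000 pairwise distances per replicate), 50 trees for the
oracle-equivalence sweep, 200 trees for the bar-count property, 20 trees ×
7 noise levels for the stability fit. These sizes were chosen so the entire
suite completes in well under a minute per experiment on a single core
while keeping replicate standard deviations of the accuracy estimates in
the few-percent range.

## Known limitations

- The descriptor is not a complete invariant: distinct trees can share a
  barcode, and `dist_bar` can vanish between distinct barcodes.
- Radius (diameter) information in SWC files is parsed but ignored.
- `branch_order` and `section_length` filters produce many ties; barcodes
  under them are valid but coarse.
- The bottleneck implementation targets desk-scale diagrams (≤ a few
  hundred points); it is exact but not tuned for large inputs.
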