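# topomorph

Topological descriptors for branching morphologies: map any rooted tree
embedded in a metric space — a neuronal reconstruction, an artificial random
tree — to a **persistence barcode**, and compare, vectorize, cluster and
classify trees through it.

Quantifying the shape of highly ramified structures such as dendritic arbors
is hard: raw point clouds are too expensive for standard topological data
analysis, and hand-picked morphometrics (branch counts, total length,
asymmetry indices) lose the correlations between features. `topomorph`
implements the middle road: a descriptor that couples the branching topology
with the embedding while discarding uninformative within-branch detail.

## The descriptor

Let *T* be a rooted tree with branch points *B*, leaves *L*, node set
*N = B ∪ L* and root *R*, and let *f* be a real-valued function on nodes
(default: radial distance from *R*, in µm). Define

    v(n) = max { f(x) : x a leaf of the subtree rooted at n }.

Starting from the leaves (where `v = f`) and walking toward the root, every
branch point kills all but its *oldest* child component — the one with the
largest *v* — and each killed component contributes one interval
`(v(child), f(branch point))` to the barcode; the surviving component passes
its *v* to the parent. The last component dies at the root with interval
`(v(R), f(R))`. The result has exactly one bar per leaf, is invariant under
rotations about the root and rigid translations (for radial *f*), and is
computed in time linear in the number of nodes. When all branches grow away
from the root it coincides with the 0-dimensional persistence of a
filtration by concentric spheres of decreasing radius centred at *R* (an
independent brute-force implementation of that filtration ships as a test
oracle).

On top of the barcode:

- **Barcode distance** `dist_bar`: integral of the absolute difference of the
  two *density profiles* (number of bars alive at each value of *f*) —
  cheap, sensitive to the short bars that distinguish morphologies.
- **Bottleneck distance**: exact classical diagram metric with diagonal
  augmentation.
- **Unweighted persistence images**: Gaussian-kernel discretizations of the
  diagram on a fixed grid, with group averages, differences, and flattening
  to feature vectors for decision-tree / SVM classification. Unweighted
  means points near the diagonal keep full mass.
- **Random-tree simulator**: a constrained stochastic generator with five
  shape parameters (depth `T_d`, branch length `B_l`, branch angle `B_a`,
  randomness `D_r`, asymmetry `A_b`).
- **Grouping machinery**: leave-one-out nearest-group classification under
  `dist_bar`, Ward clustering of distance matrices, and distance ranking of
  candidate reconstructions against a reference.

## Worked example

```python
from topomorph import PersistenceBarcode, compute_tmd, dist_bar, read_swc

tree, = read_swc("y_tree.swc")       # root, branch point at radius 4 µm,
                                     # leaves at radii 10 µm and 6 µm
barcode = compute_tmd(tree, "radial_distance")
print(sorted(barcode))               # [(6.0, 4.0), (10.0, 0.0)]

chain = PersistenceBarcode([[10.0, 0.0]])
print(dist_bar(barcode, chain))      # 2.0
```

The short branch is born at its leaf (radius 6) and dies where it merges at
the branch point (radius 4); the long branch survives to the root. Against a
single unbranched tree the density profiles differ by exactly one component
on [4, 6], hence distance 2.

Each script in `examples/` exercises one capability end to end (barcode
extraction, distances, persistence images, simulation, group classification,
ranking) and prints the numbers it computes. A thin CLI exposes the same
operations (`topomorph extract|distance|image|simulate|group-experiment|classify|rank`).

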