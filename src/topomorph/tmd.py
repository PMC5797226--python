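"""The topological morphology descriptor: tree -> persistence barcode.

Given a rooted tree embedded in a metric space and a real-valued function
``f`` on its nodes (by default the radial distance from the root), the
algorithm records one (birth, death) interval per leaf: the lifetime of the
connected component started at that leaf under the filtration induced by
``f``.  Walking from the leaves toward the root, each node ``n`` carries

    v(n) = max{ f(x) : x a leaf of the subtree rooted at n },

and at every branch point all but the oldest sibling (largest ``v``) die,
emitting the interval ``(v(sibling), f(branch point))``; the survivor hands
``v`` to its parent.  The final surviving component dies at the root with
interval ``(v(root), f(root))``.

For radial distance and trees whose branches all grow away from the root,
this is the zero-dimensional persistence of a filtration by concentric
spheres of decreasing radius; :func:`sphere_filtration_oracle` computes that
directly (quadratic, union-find) and exists as an independent cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morphology import Tree, filter_values

__all__ = [
    "PersistenceBarcode",
    "PersistenceDiagram",
    "compute_tmd",
    "sphere_filtration_oracle",
    "barcode_to_diagram",
    "save_barcode",
    "load_barcode",
    "is_outgoing",
]


@dataclass
class PersistenceBarcode:
    """Multiset of (birth, death) intervals in the units of the filter.

    Intervals keep their orientation: for radial distance, births (at leaves)
    exceed deaths (at branch points), so ``birth > death`` is the common case
    and the pair is never sorted.
    """

    intervals: np.ndarray            # (k, 2) float: birth, death
    filter_name: str = "radial_distance"

    def __post_init__(self):
        self.intervals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def births(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def deaths(self) -> np.ndarray:
        return self.intervals[:, 1]

    def sorted(self) -> "PersistenceBarcode":
        order = np.lexsort((self.intervals[:, 1], self.intervals[:, 0]))
        return PersistenceBarcode(self.intervals[order], self.filter_name)


@dataclass
class PersistenceDiagram:
    """The barcode's intervals as points (birth, death) in the plane."""

    points: np.ndarray               # (k, 2) float
    filter_name: str = "radial_distance"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.points.shape[0]


def barcode_to_diagram(barcode: PersistenceBarcode) -> PersistenceDiagram:
    """One planar point per interval; coordinates are never reordered."""
    return PersistenceDiagram(barcode.intervals.copy(), barcode.filter_name)


# ---------------------------------------------------------------------------
# The descriptor
# ---------------------------------------------------------------------------

def _reduced_parent(tree: Tree) -> dict[int, int]:
    """Parent map on the TMD node set (continuation chains contracted)."""
    root = tree.root
    keep = set(int(i) for i in tree.tmd_nodes) | {root}
    out: dict[int, int] = {}
    for n in keep:
        if n == root:
            out[n] = -1
            continue
        p = int(tree.parent[n])
        while p not in keep:
            p = int(tree.parent[p])
        out[n] = p
    return out


def compute_tmd(tree: Tree, filter_name: str = "radial_distance",
                f: np.ndarray | None = None) -> PersistenceBarcode:
    """Extract the persistence barcode of a tree under a filter function.

    Parameters
    ----------
    tree:
        The rooted embedded tree.  Continuation nodes are allowed; only
        branch points and leaves enter the computation.
    filter_name:
        One of ``radial_distance``, ``path_distance``, ``branch_order``,
        ``section_length``.
    f:
        Optional explicit per-node filter values overriding ``filter_name``.

    Returns
    -------
    PersistenceBarcode with exactly one interval per leaf.

    Notes
    -----
    Runs in time linear in the number of nodes: each TMD node is enqueued
    once, and every branch point keeps a count of unresolved children so the
    oldest-sibling selection is a constant-time bookkeeping update.
    """
    bars, _ = _tmd_with_stats(tree, filter_name, f)
    return bars


def _tmd_with_stats(tree, filter_name="radial_distance", f=None):
    if tree.n_nodes == 0:
        raise ValueError("empty tree")
    if f is None:
        f = filter_values(tree, filter_name)
    else:
        f = np.asarray(f, dtype=float)
        if f.shape != (tree.n_nodes,):
            raise ValueError("filter values must be defined on every node")
    if not np.all(np.isfinite(f)):
        raise ValueError("filter function undefined (non-finite) on some node")

    root = tree.root
    rparent = _reduced_parent(tree)
    pending: dict[int, int] = {}          # unresolved-children count per parent
    resolved: dict[int, list[tuple[float, int]]] = {}
    for n, p in rparent.items():
        if p >= 0:
            pending[p] = pending.get(p, 0) + 1
            resolved.setdefault(p, [])

    leaves = sorted((int(l) for l in tree.leaves), key=lambda l: f[l])
    if tree.n_nodes == 1:
        return PersistenceBarcode(np.array([[f[root], f[root]]]), filter_name), 1

    bars: list[tuple[float, float]] = []
    queue = list(leaves)                  # processed in increasing f order
    pops = 0
    qi = 0
    while qi < len(queue):
        n = queue[qi]
        qi += 1
        pops += 1
        v_n = f[n] if not tree.children[n] else _v_of(resolved, bars, f, n)
        p = rparent[n]
        if p == -1:
            # n is the root: emit the final surviving component
            bars.append((v_n, f[root]))
            break
        resolved[p].append((v_n, n))
        pending[p] -= 1
        if pending[p] == 0:
            queue.append(p)

    return PersistenceBarcode(np.array(bars), filter_name), pops


def _v_of(resolved, bars, f, n):
    """Resolve branch point n: kill younger siblings, return the carried v."""
    entries = resolved[n]
    # oldest sibling: max by (v, node index); among equal v the larger index
    # survives, i.e. the smaller-id sibling is killed
    m = max(range(len(entries)), key=lambda i: (entries[i][0], entries[i][1]))
    for i, (v_c, _) in enumerate(entries):
        if i != m:
            bars.append((v_c, f[n]))
    return entries[m][0]


# ---------------------------------------------------------------------------
# Concentric-sphere oracle
# ---------------------------------------------------------------------------

def is_outgoing(tree: Tree, f: np.ndarray | None = None) -> bool:
    """True iff every edge moves radially away from the root."""
    if f is None:
        f = filter_values(tree, "radial_distance")
    mask = tree.parent >= 0
    return bool(np.all(f[mask] > f[tree.parent[mask]]))


def sphere_filtration_oracle(tree: Tree) -> PersistenceBarcode:
    """Barcode from an explicit sweep of concentric spheres of decreasing radius.

    Union-find over nodes sorted by decreasing radial distance: a component
    is born at its maximal radius; when the sweeping sphere reaches a branch
    point where several components meet, all but the one with the largest
    birth die there (elder rule).  Quadratic bookkeeping is fine — this is a
    test oracle, not the production path.

    Requires every branch to be outgoing (child farther from the root than
    its parent); otherwise the sphere filtration is not equivalent to the
    descriptor and a ``ValueError`` is raised.
    """
    f = filter_values(tree, "radial_distance")
    if not is_outgoing(tree, f):
        raise ValueError("tree has a non-outgoing branch; "
                         "sphere filtration is not applicable")
    n = tree.n_nodes
    order = sorted(range(n), key=lambda i: -f[i])
    parent = tree.parent
    uf = list(range(n))
    birth = [0.0] * n
    added = [False] * n

    def find(i):
        while uf[i] != i:
            uf[i] = uf[uf[i]]
            i = uf[i]
        return i

    bars = []
    for i in order:
        added[i] = True
        neighbours = [int(parent[i])] if parent[i] >= 0 else []
        neighbours += tree.children[i]
        existing = {find(j) for j in neighbours if added[j]}
        if not existing:
            birth[i] = f[i]            # local maximum: a component is born
        else:
            survivor = max(existing, key=lambda c: (birth[c], c))
            for c in existing:
                if c != survivor:      # merge: younger components die here
                    bars.append((birth[c], f[i]))
                    uf[c] = survivor
            uf[i] = survivor
    root_comp = find(tree.root)
    bars.append((birth[root_comp], f[tree.root]))
    return PersistenceBarcode(np.array(bars), "radial_distance")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_barcode(barcode: PersistenceBarcode, path: str | Path,
                 fmt: str = "txt") -> None:
    """Write a barcode as two-column text (default) or JSON with metadata."""
    path = Path(path)
    if fmt == "txt":
        with open(path, "w") as fh:
            fh.write(f"# filter: {barcode.filter_name}\n")
            fh.write("# birth death\n")
            for b, d in barcode.intervals:
                fh.write(f"{b:.17g} {d:.17g}\n")
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump({"filter_name": barcode.filter_name,
                       "intervals": barcode.intervals.tolist()}, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_barcode(path: str | Path) -> PersistenceBarcode:
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        obj = json.loads(text)
        return PersistenceBarcode(np.array(obj["intervals"], dtype=float),
                                  obj.get("filter_name", "radial_distance"))
    filter_name = "radial_distance"
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "filter:" in line:
                filter_name = line.split("filter:", 1)[1].strip()
            continue
        if line.strip():
            b, d = line.split()[:2]
            rows.append((float(b), float(d)))
    return PersistenceBarcode(np.array(rows, dtype=float).reshape(-1, 2),
                              filter_name)
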