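"""Rooted trees embedded in 3-space, SWC I/O, and node filter functions.

A neuronal reconstruction is a rooted tree whose nodes carry coordinates in
micrometres.  The topological descriptor only ever looks at the *TMD nodes* —
branch points (>= 2 children) and leaves (no children) — but continuation
nodes (exactly 1 child) are kept in the data model because path lengths and
section lengths are computed along them.

The SWC format handled here is the standard 7-column whitespace text format::

    id type x y z radius parent

with ``#`` comments and ``parent == -1`` marking a root.  SWC type 1 (soma)
nodes are collapsed to a single root point and each soma child starts a
separate neurite tree, so one file may yield several :class:`Tree` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Tree",
    "SWCError",
    "read_swc",
    "write_swc",
    "radial_distances",
    "path_distances",
    "branch_orders",
    "section_lengths",
    "filter_values",
    "FILTER_FUNCTIONS",
]


class SWCError(ValueError):
    """Malformed SWC content or invalid tree structure."""


@dataclass
class Tree:
    """A rooted tree embedded in R^3.

    Nodes are indexed ``0..n-1``; ``parent[i]`` is the index of the parent of
    node ``i``, with ``-1`` for the single root.  ``original_ids`` preserves
    the SWC identifiers when the tree came from a file (SWC ids need not be
    contiguous); ``swc_types`` preserves the SWC type column.
    """

    coords: np.ndarray                       # (n, 3) float
    parent: np.ndarray                       # (n,) int, -1 at root
    original_ids: np.ndarray | None = None   # (n,) int
    swc_types: np.ndarray | None = None      # (n,) int
    _children: list[list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise SWCError("coords must be an (n, 3) array")
        if self.parent.shape != (self.n_nodes,):
            raise SWCError("parent must be an (n,) array")
        self.validate()

    # -- structure -----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def n_children(self, node: int) -> int:
        return len(self.children[node])

    @property
    def leaves(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]],
                        dtype=int)

    @property
    def branch_points(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes)
                         if len(self.children[i]) >= 2], dtype=int)

    @property
    def tmd_nodes(self) -> np.ndarray:
        """The TMD node set N = branch points ∪ leaves (continuations excluded)."""
        return np.array(sorted(set(self.branch_points) | set(self.leaves)),
                        dtype=int)

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise SWCError("empty tree")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise SWCError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.parent >= n) or np.any(self.parent < -1):
            raise SWCError("parent index out of range")
        # acyclic + connected: every node must reach the root
        for i in range(n):
            seen = 0
            j = i
            while self.parent[j] != -1:
                j = int(self.parent[j])
                seen += 1
                if seen > n:
                    raise SWCError("cycle in parent relation")

    # -- geometry ------------------------------------------------------------

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of the edge above each node (0 at the root)."""
        out = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        out[mask] = np.linalg.norm(
            self.coords[mask] - self.coords[self.parent[mask]], axis=1)
        return out

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Tree":
        """Return a copy with coordinates rigidly transformed (R @ x + t)."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        if translation is not None:
            xyz = xyz + np.asarray(translation)
        return Tree(xyz, self.parent.copy(),
                    None if self.original_ids is None else self.original_ids.copy(),
                    None if self.swc_types is None else self.swc_types.copy())


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def _parse_swc_lines(lines) -> list[tuple[int, int, float, float, float, float, int]]:
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            ntype = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}") from None
        rows.append((nid, ntype, x, y, z, r, pid))
    if not rows:
        raise SWCError("no data lines in SWC input")
    return rows


def read_swc(path: str | Path) -> list[Tree]:
    """Read an SWC file; return one :class:`Tree` per root-attached neurite.

    All type-1 (soma) samples are collapsed to a single root point placed at
    the first soma sample's coordinates; every child of any soma sample is
    re-attached to that point and starts its own neurite tree (each returned
    tree contains the soma root).  Files without soma samples yield one tree
    per SWC root.
    """
    with open(path) as fh:
        rows = _parse_swc_lines(fh)

    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise SWCError("duplicate node ids")
    by_id = {r[0]: r for r in rows}
    for nid, ntype, x, y, z, r, pid in rows:
        if pid != -1 and pid not in by_id:
            raise SWCError(f"node {nid}: parent id {pid} not present")

    soma_ids = [r[0] for r in rows if r[1] == 1]
    file_rank = {r[0]: i for i, r in enumerate(rows)}
    trees: list[Tree] = []

    def build(root_row, attach_rows):
        """Build one Tree from a root sample and its descendant samples."""
        reached = {root_row[0]}
        # BFS over children within attach_rows to verify reachability
        kids: dict[int, list] = {}
        for row in attach_rows:
            kids.setdefault(row[6], []).append(row)
        frontier = [root_row[0]]
        while frontier:
            cur = frontier.pop()
            for row in kids.get(cur, []):
                if row[0] in reached:
                    raise SWCError(f"node {row[0]}: multiple parents or cycle")
                reached.add(row[0])
                frontier.append(row[0])
        for row in attach_rows:
            if row[0] not in reached:
                raise SWCError(f"node {row[0]}: cyclic parent references")
        # keep the file's node order (root first) so round-trips are identities
        order = [root_row[0]] + sorted(
            (row[0] for row in attach_rows), key=file_rank.__getitem__)
        idx = {nid: i for i, nid in enumerate(order)}
        n = len(order)
        coords = np.empty((n, 3))
        parent = np.empty(n, dtype=int)
        types = np.empty(n, dtype=int)
        lookup = {row[0]: row for row in attach_rows}
        lookup[root_row[0]] = root_row
        for i, nid in enumerate(order):
            _, ntype, x, y, z, _, pid = lookup[nid]
            coords[i] = (x, y, z)
            types[i] = ntype
            parent[i] = -1 if i == 0 else idx[pid]
        return Tree(coords, parent, original_ids=np.array(order), swc_types=types)

    if soma_ids:
        soma_set = set(soma_ids)
        first = by_id[soma_ids[0]]
        soma_root = (first[0], 1, first[2], first[3], first[4], first[5], -1)
        # children of any soma sample start a neurite; re-root them on the soma point
        non_soma = [r for r in rows if r[1] != 1]
        stems = [r for r in non_soma if r[6] in soma_set or r[6] == -1]
        for stem in stems:
            stem_re = (stem[0], stem[1], stem[2], stem[3], stem[4], stem[5],
                       soma_root[0])
            desc = _descendants(stem, non_soma)
            trees.append(build(soma_root, [stem_re] + desc))
        if not stems:
            # soma-only file: a single-node tree
            trees.append(build(soma_root, []))
    else:
        roots = [r for r in rows if r[6] == -1]
        if not roots:
            raise SWCError("no root (parent -1) found")
        for root in roots:
            desc = _descendants(root, [r for r in rows if r[0] != root[0]])
            trees.append(build(root, desc))

    consumed = set()
    for t in trees:
        consumed.update(int(i) for i in t.original_ids)
    consumed.update(soma_ids)
    orphans = [r[0] for r in rows if r[0] not in consumed]
    if orphans:
        raise SWCError(f"cyclic parent references: nodes {orphans} unreachable "
                       "from any root")
    return trees


def _descendants(root_row, candidates):
    kids: dict[int, list] = {}
    for row in candidates:
        kids.setdefault(row[6], []).append(row)
    out, stack = [], [root_row[0]]
    while stack:
        cur = stack.pop()
        for row in kids.get(cur, []):
            out.append(row)
            stack.append(row[0])
    return out


def write_swc(tree: Tree, path: str | Path) -> None:
    """Write a tree as 7-column SWC (round-trips topology and coordinates)."""
    if tree.n_nodes == 0:
        raise SWCError("refusing to write an empty tree")
    types = tree.swc_types
    if types is None:
        # plain dendrite type throughout: a type-1 root with several children
        # would be collapsed as a soma on re-read and split into neurites
        types = np.full(tree.n_nodes, 3, dtype=int)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(tree.n_nodes):
            x, y, z = tree.coords[i]
            pid = tree.parent[i]
            fh.write(f"{i + 1} {types[i]} {x:.17g} {y:.17g} {z:.17g} 1.0 "
                     f"{-1 if pid < 0 else pid + 1}\n")


# ---------------------------------------------------------------------------
# Filter functions
# ---------------------------------------------------------------------------

def _check_node(tree: Tree, node: int) -> None:
    if not (0 <= node < tree.n_nodes):
        raise KeyError(f"unknown node id {node}")


def radial_distances(tree: Tree) -> np.ndarray:
    """Euclidean distance of every node from the root (micrometres)."""
    return np.linalg.norm(tree.coords - tree.coords[tree.root], axis=1)


def path_distances(tree: Tree) -> np.ndarray:
    """Summed edge length along the unique root path of every node."""
    el = tree.edge_lengths()
    out = np.zeros(tree.n_nodes)
    # parents precede children is not guaranteed; walk via explicit order
    order = _topological_order(tree)
    for i in order:
        p = tree.parent[i]
        if p >= 0:
            out[i] = out[p] + el[i]
    return out


def branch_orders(tree: Tree) -> np.ndarray:
    """Number of branch points strictly between the root and each node.

    The root itself counts as a branch point iff it has >= 2 children, so the
    order equals the number of bifurcations passed on the way out.
    """
    is_bp = np.zeros(tree.n_nodes, dtype=bool)
    is_bp[[i for i in range(tree.n_nodes) if len(tree.children[i]) >= 2]] = True
    root = tree.root
    out = np.zeros(tree.n_nodes, dtype=int)
    for i in _topological_order(tree):
        p = tree.parent[i]
        if p >= 0:
            out[i] = out[p] + (1 if (is_bp[p] and (p != root or
                                                   tree.n_children(root) >= 2))
                               else 0)
    return out


def section_lengths(tree: Tree) -> np.ndarray:
    """Length of the section (branch) ending at each node; 0 at the root.

    A section runs from the nearest ancestor TMD node (branch point or root)
    down to the node, accumulating over continuation nodes.
    """
    el = tree.edge_lengths()
    out = np.zeros(tree.n_nodes)
    root = tree.root
    for i in _topological_order(tree):
        p = tree.parent[i]
        if p < 0:
            continue
        carried = 0.0
        if p != root and tree.n_children(p) == 1:
            carried = out[p]
        out[i] = carried + el[i]
    return out


def _topological_order(tree: Tree) -> list[int]:
    order = [tree.root]
    qi = 0
    while qi < len(order):
        order.extend(tree.children[order[qi]])
        qi += 1
    return order


FILTER_FUNCTIONS = {
    "radial_distance": radial_distances,
    "path_distance": path_distances,
    "branch_order": branch_orders,
    "section_length": section_lengths,
}


def filter_values(tree: Tree, name: str = "radial_distance") -> np.ndarray:
    """Evaluate a named filter function on every node of the tree."""
    try:
        fn = FILTER_FUNCTIONS[name]
    except KeyError:
        raise ValueError(f"unknown filter function {name!r}; "
                         f"choose from {sorted(FILTER_FUNCTIONS)}") from None
    return np.asarray(fn(tree), dtype=float)


# scalar conveniences matching the operation-level interface

def radial_distance(tree: Tree, node: int) -> float:
    _check_node(tree, node)
    return float(radial_distances(tree)[node])


def path_distance(tree: Tree, node: int) -> float:
    _check_node(tree, node)
    return float(path_distances(tree)[node])


def branch_order(tree: Tree, node: int) -> int:
    _check_node(tree, node)
    return int(branch_orders(tree)[node])
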