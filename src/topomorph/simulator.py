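"""Constrained stochastic generator of artificial branching trees.

Five parameters control the shape of a generated tree:

======================  =====================================================
``tree_depth`` (T_d)    number of bifurcation levels; a symmetric tree has
                        ``2**T_d`` leaves
``branch_length`` (B_l) nominal segment length between bifurcations
``branch_angle`` (B_a)  polar deviation of each child direction from its
                        parent's direction, radians
``randomness`` (D_r)    half-width of the uniform relative noise applied to
                        every segment length and branch angle (0.10 = 10%)
``asymmetry`` (A_b)     imbalance of the depth budget at each bifurcation:
                        0 gives a full binary tree, 1 maximal imbalance (one
                        child of every bifurcation is a leaf)
======================  =====================================================

The control configuration used throughout the grouping experiments is
``T_d=5, B_l=10, B_a=pi/4, D_r=10%, A_b=0``.  Trees are fully reproducible
from their integer seed.  Nodes are placed only at the root, bifurcations
and tips (segments are straight), so every generated tree's node set equals
its TMD node set.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .morphology import Tree, write_swc

__all__ = [
    "RandomTreeParams",
    "CONTROL_PARAMS",
    "generate_random_tree",
    "generate_group",
    "expected_leaf_count",
    "make_fixture_swc",
]


@dataclass(frozen=True)
class RandomTreeParams:
    tree_depth: int = 5
    branch_length: float = 10.0
    branch_angle: float = math.pi / 4
    randomness: float = 0.10
    asymmetry: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.tree_depth < 1:
            raise ValueError("tree_depth must be >= 1")
        if self.branch_length <= 0:
            raise ValueError("branch_length must be > 0")
        if not 0.0 <= self.asymmetry <= 1.0:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.randomness < 0:
            raise ValueError("randomness must be >= 0")


CONTROL_PARAMS = RandomTreeParams()


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to u."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _child_budgets(budget: int, asymmetry: float) -> tuple[int, int]:
    """Depth budgets of the two children of a bifurcation with ``budget`` left.

    The first child keeps the full remaining depth; the second child's budget
    is shortened by ``round(asymmetry * (budget - 1))``, so asymmetry 0 gives
    a full binary tree and asymmetry 1 makes the second child a leaf.
    """
    k = budget - 1
    return k, max(0, k - int(round(asymmetry * k)))


def expected_leaf_count(tree_depth: int, asymmetry: float = 0.0) -> int:
    """Deterministic leaf count of a generated tree (structure is seed-free)."""
    def leaves(k: int) -> int:
        if k == 0:
            return 1
        b1, b2 = _child_budgets(k, asymmetry)
        return leaves(b1) + leaves(b2)
    return leaves(tree_depth)


def generate_random_tree(params: RandomTreeParams) -> Tree:
    """Grow one random binary tree embedded in 3-space.

    The root sits at the origin with a random initial direction.  Each
    bifurcation spawns two children whose directions deviate from the parent
    direction by the branch angle (noised by the randomness fraction) at
    opposite azimuths drawn uniformly, and whose segment lengths are the
    branch length with multiplicative uniform noise.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dr = params.randomness

    def noise() -> float:
        return 1.0 + rng.uniform(-dr, dr)

    coords = [np.zeros(3)]
    parent = [-1]

    u0 = rng.normal(size=3)
    u0 /= np.linalg.norm(u0)

    # explicit stack for a deterministic preorder traversal
    stack = [(0, u0, params.tree_depth)]
    while stack:
        node, direction, budget = stack.pop()
        if budget == 0:
            continue
        b1, b2 = _child_budgets(budget, params.asymmetry)
        e1, e2 = _orthonormal_frame(direction)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        children = []
        for branch_budget, azimuth in ((b1, phi), (b2, phi + math.pi)):
            theta = params.branch_angle * noise()
            length = params.branch_length * noise()
            d = (math.cos(theta) * direction
                 + math.sin(theta) * (math.cos(azimuth) * e1
                                      + math.sin(azimuth) * e2))
            d /= np.linalg.norm(d)
            idx = len(coords)
            coords.append(coords[node] + length * d)
            parent.append(node)
            children.append((idx, d, branch_budget))
        # push in reverse so the first child is processed first
        for child in reversed(children):
            stack.append(child)

    return Tree(np.asarray(coords), np.asarray(parent, dtype=int))


def generate_group(params: RandomTreeParams, n: int,
                   base_seed: int | None = None) -> list[Tree]:
    """n trees with the same shape parameters and consecutive seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    return [generate_random_tree(replace(params, seed=base_seed + i))
            for i in range(n)]


# ---------------------------------------------------------------------------
# Hand-built SWC fixtures
# ---------------------------------------------------------------------------

_SQRT20 = math.sqrt(20.0)

FIXTURES = {
    # root -> continuation -> leaf at radius 10; barcode {(10, 0)}
    "chain": (
        "1 1 0 0 0 1.0 -1\n"
        "2 3 0 0 4 1.0 1\n"
        "3 3 0 0 10 1.0 2\n"
    ),
    # branch point at radius 4, leaves at radii 10 and 6; barcode {(6,4),(10,0)}
    "y_tree": (
        "1 1 0 0 0 1.0 -1\n"
        "2 3 0 0 4 1.0 1\n"
        "3 3 0 6 8 1.0 2\n"
        f"4 3 0 {_SQRT20:.17g} 4 1.0 2\n"
    ),
    # trifurcation at radius 3, leaves at radii 5, 7, 9
    "multifurcation": (
        "1 1 0 0 0 1.0 -1\n"
        "2 3 0 0 3 1.0 1\n"
        "3 3 0 4 3 1.0 2\n"
        "4 3 0 0 7 1.0 2\n"
        f"5 3 0 {math.sqrt(81 - 9):.17g} 3 1.0 2\n"
    ),
    # an edge heading back toward the root (radius 10 -> 6)
    "non_outgoing": (
        "1 1 0 0 0 1.0 -1\n"
        "2 3 0 0 10 1.0 1\n"
        "3 3 0 4 {:.17g} 1.0 2\n".format(math.sqrt(36 - 16))
    ),
}


def make_fixture_swc(out_dir: str | Path, n_random: int = 3,
                     random_seed: int = 0) -> list[Path]:
    """Write the hand-built SWC fixtures plus a few seeded random trees.

    Deterministic: re-running with the same arguments reproduces every file
    byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    header = "# id type x y z radius parent\n"
    for name, body in FIXTURES.items():
        path = out_dir / f"{name}.swc"
        path.write_text(header + body)
        written.append(path)
    for i in range(n_random):
        tree = generate_random_tree(
            replace(CONTROL_PARAMS, seed=random_seed + i))
        path = out_dir / f"random_tree_seed{random_seed + i}.swc"
        write_swc(tree, path)
        written.append(path)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(
        {"fixtures": sorted(FIXTURES), "n_random": n_random,
         "random_seed": random_seed}, indent=1))
    written.append(manifest)
    return written
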