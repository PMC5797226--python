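"""Distances between persistence barcodes and diagrams.

Two distances are provided:

``dist_bar``
    The barcode distance used for grouping morphologies: each barcode is
    turned into its *density profile* — the integer-valued function counting,
    at every point x, how many intervals contain x (components alive at x) —
    and the distance is the integral of the absolute difference of the two
    profiles.  It is a pseudometric, cheap, and sensitive to short bars, but
    not stable under many small perturbations.

``bottleneck_distance``
    The classical bottleneck distance between persistence diagrams with
    diagonal augmentation: the smallest r such that a perfect matching
    exists in which every matched pair is within L-infinity distance r and
    every unmatched point is within r of the diagonal.  Computed exactly by
    binary search over candidate radii with a bipartite-matching feasibility
    test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .tmd import PersistenceBarcode, PersistenceDiagram, barcode_to_diagram

__all__ = [
    "DensityProfile",
    "DistanceMatrix",
    "density_profile",
    "dist_bar",
    "bottleneck_distance",
    "distance_matrix",
]


@dataclass
class DensityProfile:
    """Piecewise-constant count of barcode intervals alive at each point.

    ``counts[i]`` is the value on the cell ``[breakpoints[i],
    breakpoints[i+1]]``; outside the outermost breakpoints the profile is 0.
    Point queries use closed spans (an interval contains both its endpoints).
    """

    breakpoints: np.ndarray          # (m,) sorted
    counts: np.ndarray               # (m-1,) non-negative int
    intervals: np.ndarray            # (k, 2) source spans [lo, hi]

    def __call__(self, x: float) -> int:
        """Number of intervals whose closed span contains x."""
        if len(self.intervals) == 0:
            return 0
        lo, hi = self.intervals[:, 0], self.intervals[:, 1]
        return int(np.sum((lo <= x) & (x <= hi)))


def _spans(barcode: PersistenceBarcode) -> np.ndarray:
    """Closed spans [min(b,d), max(b,d)] of a barcode's intervals."""
    iv = barcode.intervals
    if len(iv) == 0:
        return np.empty((0, 2))
    return np.column_stack([iv.min(axis=1), iv.max(axis=1)])


def density_profile(barcode: PersistenceBarcode) -> DensityProfile:
    """Exact profile via an endpoint sweep — no binning, no free parameters."""
    spans = _spans(barcode)
    if len(spans) == 0:
        return DensityProfile(np.zeros(1), np.zeros(0, dtype=int), spans)
    bp = np.unique(spans.ravel())
    if len(bp) == 1:
        return DensityProfile(bp, np.zeros(0, dtype=int), spans)
    mids = 0.5 * (bp[:-1] + bp[1:])
    counts = ((spans[:, [0]] <= mids) & (mids <= spans[:, [1]])).sum(axis=0)
    return DensityProfile(bp, counts.astype(int), spans)


def dist_bar(b1: PersistenceBarcode, b2: PersistenceBarcode) -> float:
    """Integral of |profile1 - profile2| over the union of supports.

    Exact merged-breakpoint sweep; symmetric, non-negative, zero for
    identical barcodes.  Both barcodes must come from the same filter
    function (the units of the integral are those of the filter).
    """
    if b1.filter_name != b2.filter_name:
        raise ValueError(f"cannot compare barcodes from different filters: "
                         f"{b1.filter_name!r} vs {b2.filter_name!r}")
    s1, s2 = _spans(b1), _spans(b2)
    bp = np.unique(np.concatenate([s1.ravel(), s2.ravel()]))
    if len(bp) < 2:
        return 0.0
    mids = 0.5 * (bp[:-1] + bp[1:])
    widths = np.diff(bp)

    def counts(spans):
        if len(spans) == 0:
            return np.zeros_like(mids)
        return ((spans[:, [0]] <= mids) & (mids <= spans[:, [1]])).sum(axis=0)

    return float(np.sum(np.abs(counts(s1) - counts(s2)) * widths))


# ---------------------------------------------------------------------------
# Bottleneck distance
# ---------------------------------------------------------------------------

def _diag_costs(points: np.ndarray) -> np.ndarray:
    """L-infinity distance of each point to its diagonal projection."""
    if len(points) == 0:
        return np.zeros(0)
    return np.abs(points[:, 0] - points[:, 1]) / 2.0


def _feasible(p1, p2, d1c, d2c, r) -> bool:
    """Is there a perfect matching with no pair farther than r?

    Left vertices: points of D1 then diagonal slots for D2's points.
    Right vertices: points of D2 then diagonal slots for D1's points.
    Diagonal-diagonal pairings cost 0 and are always allowed.
    """
    n1, n2 = len(p1), len(p2)
    rows, cols = [], []
    if n1 and n2:
        cross = np.max(np.abs(p1[:, None, :] - p2[None, :, :]), axis=2)
        ii, jj = np.nonzero(cross <= r)
        rows.extend(ii.tolist())
        cols.extend(jj.tolist())
    for i in np.nonzero(d1c <= r)[0]:        # D1 point -> its diagonal slot
        rows.append(int(i))
        cols.append(n2 + int(i))
    for j in np.nonzero(d2c <= r)[0]:        # diagonal slot -> D2 point
        rows.append(n1 + int(j))
        cols.append(int(j))
    for j in range(n2):                      # diagonal-diagonal, always free
        for i in range(n1):
            rows.append(n1 + j)
            cols.append(n2 + i)
    size = n1 + n2
    graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                       shape=(size, size))
    match = maximum_bipartite_matching(graph, perm_type="column")
    return bool(np.all(match >= 0))


def bottleneck_distance(d1: PersistenceDiagram | PersistenceBarcode,
                        d2: PersistenceDiagram | PersistenceBarcode) -> float:
    """Exact bottleneck distance with diagonal augmentation.

    Points are used with their stored orientation (birth may exceed death);
    the diagonal projection of (b, d) is ((b+d)/2, (b+d)/2) at cost |b-d|/2,
    which treats points on either side of the diagonal symmetrically.
    """
    if isinstance(d1, PersistenceBarcode):
        d1 = barcode_to_diagram(d1)
    if isinstance(d2, PersistenceBarcode):
        d2 = barcode_to_diagram(d2)
    p1, p2 = d1.points, d2.points
    if len(p1) == 0 and len(p2) == 0:
        return 0.0
    d1c, d2c = _diag_costs(p1), _diag_costs(p2)
    candidates = [0.0]
    candidates.extend(d1c.tolist())
    candidates.extend(d2c.tolist())
    if len(p1) and len(p2):
        cross = np.max(np.abs(p1[:, None, :] - p2[None, :, :]), axis=2)
        candidates.extend(cross.ravel().tolist())
    cand = np.unique(np.asarray(candidates))
    lo, hi = 0, len(cand) - 1
    if _feasible(p1, p2, d1c, d2c, cand[lo]):
        return float(cand[lo])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _feasible(p1, p2, d1c, d2c, cand[mid]):
            hi = mid
        else:
            lo = mid
    return float(cand[hi])


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

METRICS = {
    "dbar": dist_bar,
    "bottleneck": bottleneck_distance,
}


@dataclass
class DistanceMatrix:
    labels: list
    values: np.ndarray               # (n, n) symmetric, zero diagonal
    metric: str = "dbar"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(sep.join(["#label"] + [str(l) for l in self.labels]) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(sep.join([str(lab)] + [f"{v:.17g}" for v in row]) + "\n")


def distance_matrix(items: list[PersistenceBarcode], metric: str = "dbar",
                    labels: list | None = None) -> DistanceMatrix:
    """All pairwise distances between barcodes under the chosen metric."""
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    try:
        fn = METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}; "
                         f"choose from {sorted(METRICS)}") from None
    n = len(items)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(items[i], items[j])
    if labels is None:
        labels = list(range(n))
    return DistanceMatrix(labels, out, metric)
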