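"""Unweighted persistence images: diagram -> pixel matrix -> feature vector.

A persistence diagram is rendered as a sum of isotropic Gaussian kernels,
one per diagram point, evaluated at the centres of a fixed (birth, death)
pixel grid.  Crucially the image is *unweighted*: no point is down-weighted
by its persistence, so short components — points near the diagonal, which
carry much of the discriminative signal for branching morphologies — keep
their full mass.  Images on a common grid can be averaged per group and
subtracted to visualise and quantify group differences, and flattened into
vectors for off-the-shelf classifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tmd import PersistenceBarcode, PersistenceDiagram, barcode_to_diagram

__all__ = [
    "PersistenceImage",
    "persistence_image",
    "average_image",
    "image_difference",
    "image_to_vector",
    "vector_to_image",
    "scott_bandwidth",
    "common_bounds",
]


@dataclass
class PersistenceImage:
    """Pixel matrix on a fixed (birth, death) grid.

    ``pixels[i, j]`` is the kernel sum at the centre of the cell in death-row
    ``i`` and birth-column ``j``; rows run from ``death_range[0]`` upward.
    Images are comparable (averagable, subtractable) only when bounds,
    resolution, and bandwidth all match.
    """

    pixels: np.ndarray               # (H, W)
    birth_range: tuple[float, float]
    death_range: tuple[float, float]
    bandwidth: float


    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.pixels.shape

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinates (births (W,), deaths (H,))."""
        h, w = self.pixels.shape
        b = _centers(*self.birth_range, w)
        d = _centers(*self.death_range, h)
        return b, d

    def _compatible(self, other: "PersistenceImage") -> None:
        if (self.pixels.shape != other.pixels.shape
                or self.birth_range != other.birth_range
                or self.death_range != other.death_range
                or self.bandwidth != other.bandwidth):
            raise ValueError("images live on different grids "
                             "(bounds/resolution/bandwidth mismatch)")


def _centers(lo: float, hi: float, n: int) -> np.ndarray:
    edges = np.linspace(lo, hi, n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule bandwidth for a 2-D kernel density estimate.

    ``n**(-1/6)`` times the mean of the per-axis standard deviations; falls
    back to 5% of the coordinate span (or 1.0) when the spread is degenerate.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(points)
    if n == 0:
        return 1.0
    stds = points.std(axis=0, ddof=1) if n > 1 else np.zeros(2)
    s = float(np.mean(stds))
    if s <= 0:
        span = float(points.max() - points.min())
        return 0.05 * span if span > 0 else 1.0
    return s * n ** (-1.0 / 6.0)


def common_bounds(diagrams, pad: float = 0.05):
    """Shared (birth_range, death_range) for a cohort, padded by ``pad``.

    Bounds must be fixed across a cohort before images are averaged or fed
    to a classifier; this computes the min/max of births and deaths over all
    diagrams and pads each axis by a fraction of its span.
    """
    pts = np.vstack([d.points if isinstance(d, PersistenceDiagram)
                     else np.asarray(d.intervals) for d in diagrams])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    lo = lo - pad * span
    hi = hi + pad * span
    return (float(lo[0]), float(hi[0])), (float(lo[1]), float(hi[1]))


def persistence_image(diagram: PersistenceDiagram | PersistenceBarcode,
                      bounds=None, resolution: tuple[int, int] = (100, 100),
                      bandwidth: float | None = None) -> PersistenceImage:
    """Render a diagram as an unweighted persistence image.

    Parameters
    ----------
    diagram:
        Diagram (or barcode, converted on the fly).
    bounds:
        ``(birth_range, death_range)``; defaults to the diagram's own extent
        padded by 5%.  Use :func:`common_bounds` for cohorts.
    resolution:
        ``(H, W)`` pixel counts, each >= 2.
    bandwidth:
        Gaussian kernel standard deviation in filter units; defaults to
        Scott's rule on the diagram's points.  Each point contributes a
        density of unit integral over the plane (mass falling outside the
        bounds is simply truncated), so total pixel mass approximates the
        number of diagram points times the cell area factor.
    """
    if isinstance(diagram, PersistenceBarcode):
        diagram = barcode_to_diagram(diagram)
    pts = diagram.points
    if bounds is None:
        if len(pts) == 0:
            bounds = ((0.0, 1.0), (0.0, 1.0))
        else:
            bounds = common_bounds([diagram])
    (b_lo, b_hi), (d_lo, d_hi) = bounds
    h, w = resolution
    if h < 2 or w < 2:
        raise ValueError("resolution must be at least 2x2")
    if b_hi <= b_lo or d_hi <= d_lo:
        raise ValueError("degenerate bounds")
    if bandwidth is None:
        bandwidth = scott_bandwidth(pts)
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")

    img = np.zeros((h, w))
    if len(pts):
        bb = _centers(b_lo, b_hi, w)
        dd = _centers(d_lo, d_hi, h)
        norm = 1.0 / (2.0 * np.pi * bandwidth ** 2)
        gb = np.exp(-0.5 * ((bb[None, :] - pts[:, 0:1]) / bandwidth) ** 2)
        gd = np.exp(-0.5 * ((dd[None, :] - pts[:, 1:2]) / bandwidth) ** 2)
        img = norm * np.einsum("kh,kw->hw", gd, gb)
    return PersistenceImage(img, (float(b_lo), float(b_hi)),
                            (float(d_lo), float(d_hi)), float(bandwidth))


def average_image(images: list[PersistenceImage]) -> PersistenceImage:
    """Elementwise mean of images on a shared grid (the group-average image)."""
    if not images:
        raise ValueError("need at least one image")
    first = images[0]
    for other in images[1:]:
        first._compatible(other)
    mean = np.mean([im.pixels for im in images], axis=0)
    return PersistenceImage(mean, first.birth_range, first.death_range,
                            first.bandwidth)


def image_difference(a: PersistenceImage, b: PersistenceImage) -> PersistenceImage:
    """Signed elementwise difference a - b (for group comparisons)."""
    a._compatible(b)
    return PersistenceImage(a.pixels - b.pixels, a.birth_range, a.death_range,
                            a.bandwidth)


def image_to_vector(image: PersistenceImage) -> np.ndarray:
    """Row-major flattening to a length H*W feature vector."""
    return image.pixels.ravel().copy()


def vector_to_image(vector: np.ndarray, like: PersistenceImage) -> PersistenceImage:
    """Inverse of :func:`image_to_vector` given a template image's grid."""
    h, w = like.pixels.shape
    return PersistenceImage(np.asarray(vector, dtype=float).reshape(h, w),
                            like.birth_range, like.death_range, like.bandwidth)


def save_image(image: PersistenceImage, path: str | Path) -> None:
    """Delimited matrix text plus a JSON sidecar with the grid metadata."""
    path = Path(path)
    np.savetxt(path, image.pixels)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"birth_range": list(image.birth_range),
                   "death_range": list(image.death_range),
                   "bandwidth": image.bandwidth,
                   "resolution": list(image.pixels.shape)}, fh)


def load_image(path: str | Path) -> PersistenceImage:
    path = Path(path)
    pixels = np.loadtxt(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    return PersistenceImage(pixels, tuple(meta["birth_range"]),
                            tuple(meta["death_range"]), meta["bandwidth"])
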