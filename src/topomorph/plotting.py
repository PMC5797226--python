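"""Basic plots: barcode, diagram, persistence image, dendrogram.

matplotlib is imported lazily so the rest of the package works without it.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_barcode(barcode, ax=None):
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    for i, (b, d) in enumerate(sorted(barcode, key=lambda iv: min(iv))):
        ax.plot([min(b, d), max(b, d)], [i, i], lw=1.2, color="C0")
    ax.set_xlabel(f"{barcode.filter_name}")
    ax.set_ylabel("component")
    return ax


def plot_diagram(diagram, ax=None):
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    pts = diagram.points
    ax.scatter(pts[:, 0], pts[:, 1], s=12)
    lo = float(pts.min()) if len(pts) else 0.0
    hi = float(pts.max()) if len(pts) else 1.0
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.5)
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    return ax


def plot_image(image, ax=None):
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(image.pixels, origin="lower", aspect="auto",
              extent=[*image.birth_range, *image.death_range], cmap="viridis")
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    return ax


def plot_dendrogram(linkage_matrix, labels=None, ax=None):
    from scipy.cluster.hierarchy import dendrogram
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    dendrogram(linkage_matrix, labels=labels, ax=ax)
    return ax
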