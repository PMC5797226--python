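"""Grouping, clustering, supervised classification, and ranking of barcodes.

The central grouping device is a nearest-group rule under the barcode
distance: a query barcode is assigned to the group whose members have the
smallest mean ``dist_bar`` to it (leave-one-out when the query belongs to
the cohort).  On top of that sit Ward hierarchical clustering of distance
matrices, supervised classifiers (decision tree / RBF SVM) on persistence-
image vectors, and distance-based ranking of candidate reconstructions
against a reference morphology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .images import common_bounds, image_to_vector, persistence_image
from .metrics import DistanceMatrix, dist_bar, distance_matrix
from .simulator import RandomTreeParams, generate_group
from .tmd import PersistenceBarcode, compute_tmd

__all__ = [
    "LabeledCohort",
    "AccuracyReport",
    "assign_to_group",
    "ward_clustering",
    "grouping_accuracy",
    "train_image_classifier",
    "rank_reconstructions",
    "cohort_images",
]


@dataclass
class LabeledCohort:
    """Items (barcodes or images) with one group label each."""

    items: list
    labels: list
    provenance: list | None = None

    def __post_init__(self):
        if len(self.items) != len(self.labels):
            raise ValueError("one label per item required")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def classes(self) -> list:
        return sorted(set(self.labels))


@dataclass
class AccuracyReport:
    accuracy: float                      # fraction correct
    confusion: np.ndarray                # (k, k), rows = true class
    classes: list
    n_items: int
    protocol: dict = field(default_factory=dict)
    accuracy_sd: float | None = None     # across trial replicates, if any

    def __str__(self) -> str:
        sd = "" if self.accuracy_sd is None else f" ± {self.accuracy_sd:.3f}"
        return (f"accuracy {self.accuracy:.3f}{sd} over {self.n_items} items, "
                f"classes {self.classes}")


# ---------------------------------------------------------------------------
# Nearest-group assignment under dist_bar
# ---------------------------------------------------------------------------

def assign_to_group(query: PersistenceBarcode, cohort: LabeledCohort,
                    exclude_index: int | None = None):
    """Label of the group with the smallest mean barcode distance to the query.

    If the query is a cohort member, pass its index as ``exclude_index`` (or
    rely on identity detection) so it does not vote for itself — the
    leave-one-out protocol.  Ties break to the lexicographically first label.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    scores: dict = {}
    counts: dict = {}
    for i, (item, label) in enumerate(zip(cohort.items, cohort.labels)):
        if i == exclude_index or item is query:
            continue
        scores[label] = scores.get(label, 0.0) + dist_bar(query, item)
        counts[label] = counts.get(label, 0) + 1
    if not scores:
        raise ValueError("no cohort members left after exclusion")
    means = {lab: scores[lab] / counts[lab] for lab in scores}
    return min(sorted(means), key=lambda lab: means[lab])


def _loo_assignments(barcodes: list, labels: list) -> list:
    """Leave-one-out nearest-group labels for every member of a cohort.

    Computes the full pairwise distance matrix once, then takes group means
    excluding the diagonal — equivalent to calling ``assign_to_group`` per
    item but quadratic instead of cubic in cohort size.
    """
    n = len(barcodes)
    dm = distance_matrix(barcodes, "dbar").values
    labels_arr = np.asarray(labels)
    classes = sorted(set(labels))
    out = []
    for i in range(n):
        best_lab, best = None, np.inf
        for lab in classes:
            mask = labels_arr == lab
            mask_i = mask.copy()
            mask_i[i] = False
            if not mask_i.any():
                continue
            mean = dm[i, mask_i].mean()
            if mean < best:
                best, best_lab = mean, lab
        out.append(best_lab)
    return out


# ---------------------------------------------------------------------------
# Ward clustering of a distance matrix
# ---------------------------------------------------------------------------

def ward_clustering(dm: DistanceMatrix, k: int):
    """Agglomerative Ward clustering on a precomputed distance matrix.

    Returns ``(assignment, linkage_matrix)``; the linkage matrix is in scipy
    dendrogram form for plotting.  ``k`` must satisfy ``1 <= k <= n``.
    """
    n = dm.values.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} items")
    condensed = squareform(dm.values, checks=False)
    Z = linkage(condensed, method="ward")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    return assignment, Z


# ---------------------------------------------------------------------------
# Grouping-accuracy experiment on simulated trees
# ---------------------------------------------------------------------------

def grouping_accuracy(groups: list[RandomTreeParams], n_per_group: int = 20,
                      n_trials: int = 10, seed: int = 0,
                      filter_name: str = "radial_distance") -> AccuracyReport:
    """Leave-one-out nearest-group accuracy on freshly simulated cohorts.

    For each trial, every parameter set generates ``n_per_group`` trees with
    distinct seeds; barcodes are extracted with the given filter; each tree
    is assigned to the group with the smallest mean barcode distance (its
    own barcode excluded).  The report carries the mean and standard
    deviation of the per-trial accuracies and the summed confusion matrix.
    """
    if len(groups) < 1:
        raise ValueError("need at least one parameter set")
    if len({(g.tree_depth, g.branch_length, g.branch_angle, g.randomness,
             g.asymmetry) for g in groups}) < len(groups):
        import warnings
        warnings.warn("some groups have identical parameters; "
                      "accuracy will be near chance", stacklevel=2)
    classes = list(range(len(groups)))
    accs = []
    confusion = np.zeros((len(groups), len(groups)), dtype=int)
    stride = n_per_group * len(groups)
    for t in range(n_trials):
        barcodes, labels = [], []
        for g, params in enumerate(groups):
            base = seed + t * stride + g * n_per_group
            for tree in generate_group(params, n_per_group, base_seed=base):
                barcodes.append(compute_tmd(tree, filter_name))
                labels.append(g)
        predicted = _loo_assignments(barcodes, labels)
        correct = sum(p == l for p, l in zip(predicted, labels))
        accs.append(correct / len(labels))
        for l, p in zip(labels, predicted):
            confusion[l, p] += 1
    return AccuracyReport(
        accuracy=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if n_trials > 1 else None,
        confusion=confusion,
        classes=classes,
        n_items=n_per_group * len(groups) * n_trials,
        protocol={"n_per_group": n_per_group, "n_trials": n_trials,
                  "seed": seed, "filter": filter_name,
                  "rule": "leave-one-out nearest group (mean dist_bar)"})


# ---------------------------------------------------------------------------
# Supervised classification on persistence-image vectors
# ---------------------------------------------------------------------------

def cohort_images(barcodes: list[PersistenceBarcode], resolution=(20, 20),
                  bandwidth: float | None = None):
    """Persistence images of a cohort on one shared grid (required before
    averaging or classification)."""
    bounds = common_bounds(barcodes)
    if bandwidth is None:
        pooled = np.vstack([b.intervals for b in barcodes if len(b)])
        from .images import scott_bandwidth
        bandwidth = scott_bandwidth(pooled)
    return [persistence_image(b, bounds=bounds, resolution=resolution,
                              bandwidth=bandwidth) for b in barcodes]


def train_image_classifier(cohort: LabeledCohort, method: str = "decision_tree",
                           split: float = 0.25, seed: int = 0,
                           merge: dict | None = None):
    """Fit a supervised classifier on flattened persistence-image vectors.

    ``split`` is the held-out test fraction of a stratified split; ``merge``
    optionally maps labels onto merged superclasses (e.g. two subtypes into
    one) before fitting.  Returns ``(classifier, AccuracyReport)`` with the
    held-out accuracy and confusion matrix.
    """
    labels = list(cohort.labels)
    if merge:
        labels = [merge.get(l, l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    first = cohort.items[0]
    for im in cohort.items[1:]:
        first._compatible(im)
    X = np.vstack([image_to_vector(im) for im in cohort.items])
    y = np.asarray(labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=split, random_state=seed, stratify=y)
    if method == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif method == "svm":
        clf = SVC(kernel="rbf", random_state=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    report = AccuracyReport(
        accuracy=float(np.mean(pred == y_te)),
        confusion=_sk_confusion(y_te, pred, labels=classes),
        classes=classes,
        n_items=len(y_te),
        protocol={"method": method, "split": split, "seed": seed,
                  "merge": merge or {}})
    return clf, report


# ---------------------------------------------------------------------------
# Ranking of reconstructions against a reference
# ---------------------------------------------------------------------------

def rank_reconstructions(reference: PersistenceBarcode,
                         candidates: list[PersistenceBarcode],
                         ids: list | None = None):
    """Candidates sorted by ascending barcode distance to the reference.

    Returns ``[(id, distance), ...]``; ties break on the candidate id so the
    ranking is independent of input order.
    """
    if ids is None:
        ids = list(range(len(candidates)))
    scored = [(ids[i], dist_bar(reference, c)) for i, c in enumerate(candidates)]
    return sorted(scored, key=lambda t: (t[1], str(t[0])))
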