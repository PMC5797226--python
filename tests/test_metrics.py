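import itertools

import numpy as np
import pytest

from topomorph import (PersistenceBarcode, PersistenceDiagram,
                       bottleneck_distance, density_profile, dist_bar,
                       distance_matrix)
from conftest import random_barcode


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_dist_bar(b1, b2, n=100_000):
    """Riemann-sum quadrature of |profile1 - profile2| on a dense grid."""
    pts = np.concatenate([b1.intervals.ravel(), b2.intervals.ravel()])
    lo, hi = pts.min(), pts.max()
    xs = np.linspace(lo, hi, n)
    dx = xs[1] - xs[0]

    def count(bc, xs):
        lo_ = bc.intervals.min(axis=1)
        hi_ = bc.intervals.max(axis=1)
        return ((lo_[:, None] <= xs) & (xs <= hi_[:, None])).sum(axis=0)

    return float(np.sum(np.abs(count(b1, xs) - count(b2, xs))) * dx)


def brute_bottleneck(p1, p2):
    """Exhaustive minimum over all matchings with diagonal augmentation.

    Every point of each diagram is either matched to a point of the other
    diagram (injectively) or sent to the diagonal.  Feasible only for tiny
    diagrams.
    """
    p1, p2 = np.atleast_2d(p1), np.atleast_2d(p2)
    n1, n2 = len(p1), len(p2)
    diag1 = np.abs(p1[:, 0] - p1[:, 1]) / 2 if n1 else np.zeros(0)
    diag2 = np.abs(p2[:, 0] - p2[:, 1]) / 2 if n2 else np.zeros(0)
    best = np.inf
    for k in range(0, min(n1, n2) + 1):
        for sub1 in itertools.combinations(range(n1), k):
            for sub2 in itertools.permutations(range(n2), k):
                cost = 0.0
                for i, j in zip(sub1, sub2):
                    cost = max(cost, np.max(np.abs(p1[i] - p2[j])))
                for i in set(range(n1)) - set(sub1):
                    cost = max(cost, diag1[i])
                for j in set(range(n2)) - set(sub2):
                    cost = max(cost, diag2[j])
                best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# density profiles
# ---------------------------------------------------------------------------

class TestDensityProfile:
    def test_single_bar(self):
        prof = density_profile(PersistenceBarcode([[10.0, 0.0]]))
        assert prof(5.0) == 1
        assert prof(0.0) == 1 and prof(10.0) == 1
        assert prof(10.1) == 0 and prof(-0.1) == 0

    def test_two_bars_endpoint_sweep(self):
        prof = density_profile(PersistenceBarcode([[10, 0], [6, 4]]))
        assert prof(5.0) == 2
        assert prof(2.0) == 1 and prof(8.0) == 1
        assert np.array_equal(prof.breakpoints, [0, 4, 6, 10])
        assert np.array_equal(prof.counts, [1, 2, 1])

    def test_empty_barcode(self):
        prof = density_profile(PersistenceBarcode(np.empty((0, 2))))
        assert prof(0.0) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_max_matches_brute_force_grid(self, seed):
        rng = np.random.default_rng(seed)
        bc = random_barcode(rng, n_bars=15)
        prof = density_profile(bc)
        xs = np.linspace(bc.intervals.min(), bc.intervals.max(), 5000)
        brute_max = max(prof(x) for x in xs)
        assert prof.counts.max() == brute_max


# ---------------------------------------------------------------------------
# dist_bar
# ---------------------------------------------------------------------------

class TestDistBar:
    def test_identical_is_zero(self, control_tree):
        from topomorph import compute_tmd
        bc = compute_tmd(control_tree)
        assert dist_bar(bc, bc) == 0.0

    def test_worked_value(self):
        assert dist_bar(PersistenceBarcode([[10.0, 0.0]]),
                        PersistenceBarcode([[6.0, 0.0]])) == pytest.approx(4.0)

    def test_filter_mismatch_raises(self):
        b1 = PersistenceBarcode([[1, 0]], "radial_distance")
        b2 = PersistenceBarcode([[1, 0]], "path_distance")
        with pytest.raises(ValueError, match="different filters"):
            dist_bar(b1, b2)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_grid_quadrature(self, seed):
        rng = np.random.default_rng(100 + seed)
        b1, b2 = random_barcode(rng), random_barcode(rng)
        assert dist_bar(b1, b2) == pytest.approx(grid_dist_bar(b1, b2),
                                                 abs=1e-2)

    @pytest.mark.parametrize("seed", range(20))
    def test_pseudometric_axioms(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b, c = (random_barcode(rng) for _ in range(3))
        dab, dba = dist_bar(a, b), dist_bar(b, a)
        assert dab == dba >= 0
        assert dist_bar(a, c) <= dab + dist_bar(b, c) + 1e-9


# ---------------------------------------------------------------------------
# bottleneck distance
# ---------------------------------------------------------------------------

class TestBottleneck:
    def test_identical_is_zero(self):
        d = PersistenceDiagram([[10, 0], [6, 4]])
        assert bottleneck_distance(d, d) == 0.0

    def test_worked_value_vs_brute_force(self):
        d1, d2 = PersistenceDiagram([[10.0, 0.0]]), PersistenceDiagram([[10.0, 2.0]])
        assert bottleneck_distance(d1, d2) == pytest.approx(2.0)
        assert brute_bottleneck(d1.points, d2.points) == pytest.approx(2.0)

    def test_empty_diagrams(self):
        e = PersistenceDiagram(np.empty((0, 2)))
        assert bottleneck_distance(e, e) == 0.0
        d = PersistenceDiagram([[6.0, 2.0]])
        # the lone point must go to the diagonal at cost |6-2|/2
        assert bottleneck_distance(d, e) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_matching(self, seed):
        rng = np.random.default_rng(300 + seed)
        d1 = PersistenceDiagram(rng.uniform(0, 10, size=(int(rng.integers(1, 4)), 2)))
        d2 = PersistenceDiagram(rng.uniform(0, 10, size=(int(rng.integers(1, 4)), 2)))
        assert bottleneck_distance(d1, d2) == pytest.approx(
            brute_bottleneck(d1.points, d2.points), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_axioms_small_instances(self, seed):
        rng = np.random.default_rng(400 + seed)
        ds = [PersistenceDiagram(rng.uniform(0, 10, size=(3, 2)))
              for _ in range(3)]
        a, b, c = ds
        assert bottleneck_distance(a, b) == pytest.approx(
            bottleneck_distance(b, a))
        assert (bottleneck_distance(a, c)
                <= bottleneck_distance(a, b) + bottleneck_distance(b, c) + 1e-9)

    @pytest.mark.parametrize("eps", [1e-3, 1e-2, 1e-1])
    def test_perturbation_stability(self, eps):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 50, size=(12, 2))
        d1 = PersistenceDiagram(pts)
        d2 = PersistenceDiagram(pts + rng.uniform(-eps, eps, pts.shape))
        assert bottleneck_distance(d1, d2) <= eps + 1e-12


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_two_identical_barcodes(self):
        b = PersistenceBarcode([[10, 0]])
        dm = distance_matrix([b, PersistenceBarcode([[10, 0]])])
        assert np.array_equal(dm.values, np.zeros((2, 2)))

    def test_entries_equal_pairwise_metric(self):
        rng = np.random.default_rng(5)
        items = [random_barcode(rng) for _ in range(4)]
        dm = distance_matrix(items, "dbar")
        for i in range(4):
            for j in range(4):
                assert dm.values[i, j] == pytest.approx(
                    dist_bar(items[i], items[j]))
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_unknown_metric(self):
        b = PersistenceBarcode([[1, 0]])
        with pytest.raises(ValueError, match="unknown metric"):
            distance_matrix([b, b], "wasserstein")

    def test_depth_groups_separate(self):
        """Between-group mean distance exceeds within-group mean distance."""
        from dataclasses import replace
        from topomorph import CONTROL_PARAMS, compute_tmd, generate_group
        bcs, labs = [], []
        for g, depth in enumerate([4, 5, 6]):
            params = replace(CONTROL_PARAMS, tree_depth=depth)
            for t in generate_group(params, 5, base_seed=g * 5):
                bcs.append(compute_tmd(t))
                labs.append(g)
        dm = distance_matrix(bcs).values
        labs = np.array(labs)
        same = dm[labs[:, None] == labs[None, :]]
        diff = dm[labs[:, None] != labs[None, :]]
        assert diff.mean() > same[same > 0].mean()

    def test_to_text(self, tmp_path):
        b = PersistenceBarcode([[10, 0]])
        dm = distance_matrix([b, b, b], labels=["a", "b", "c"])
        p = tmp_path / "dm.tsv"
        dm.to_text(p)
        lines = p.read_text().splitlines()
        assert lines[0].split("\t")[1:] == ["a", "b", "c"]
        assert len(lines) == 4
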