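import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgascape.io_formats import make_hit
from rgascape.nj_phylogeny import (
    DistanceMatrix,
    distances_from_hits,
    group_cut,
    neighbor_joining,
    read_newick,
    to_newick,
    write_newick,
)


def hit(q, s, identity):
    return make_hit(q, s, identity, 95, 1e-50, 200.0, 100, 100, 95, 95)


class TestDistancesFromHits:
    def test_identity_to_distance(self):
        dm = distances_from_hits([hit("a", "b", 80.0)], ["a", "b"])
        assert dm.d[0, 1] == pytest.approx(0.20)

    def test_missing_pair_defaults_to_one(self):
        dm = distances_from_hits([], ["a", "b"])
        assert dm.d[0, 1] == 1.0

    def test_asymmetric_hits_symmetrised_by_min(self):
        dm = distances_from_hits([hit("a", "b", 80.0), hit("b", "a", 90.0)], ["a", "b"])
        assert dm.d[0, 1] == pytest.approx(0.10)
        assert dm.d[1, 0] == pytest.approx(0.10)

    def test_diagonal_zero(self):
        dm = distances_from_hits([hit("a", "a", 50.0)], ["a", "b"])
        assert dm.d[0, 0] == 0.0


class TestDistanceMatrixValidation:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, np.inf], [np.inf, 0.0]]))


def tips_distance_matrix(tree, labels):
    dm = tree.tip_tip_distances()
    idx = {name: i for i, name in enumerate(dm.ids)}
    n = len(labels)
    out = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = dm.data[idx[a], idx[b]]
    return out


def random_additive_matrix(rng, n):
    """Random unrooted binary tree with positive branch lengths -> its exact
    leaf distance matrix (the additive oracle)."""
    labels = [f"t{i}" for i in range(n)]
    # random sequential joining: path lengths accumulated per pair
    nodes = {l: {l: 0.0} for l in labels}  # node -> leaf -> distance
    active = list(labels)
    dist = {}
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        merged = {}
        for leaf, d in nodes[a].items():
            merged[leaf] = d + la
        for leaf, d in nodes[b].items():
            merged[leaf] = d + lb
        for x in nodes[a]:
            for y in nodes[b]:
                dist[frozenset((x, y))] = nodes[a][x] + la + nodes[b][y] + lb
        key = f"#{len(nodes)}"
        nodes[key] = merged
        active = [x for x in active if x not in (a, b)] + [key]
    a, b = active
    lab = rng.uniform(0.1, 1.0)
    for x in nodes[a]:
        for y in nodes[b]:
            dist[frozenset((x, y))] = nodes[a][x] + nodes[b][y] + lab
    d = np.zeros((n, n))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                d[i, j] = dist[frozenset((x, y))]
    return DistanceMatrix(labels, d)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_edge_count_invariant(self):
        rng = np.random.default_rng(4)
        for n in (4, 5, 6, 8):
            tree = neighbor_joining(random_additive_matrix(rng, n))
            n_edges = sum(1 for _ in tree.traverse(include_self=False))
            assert n_edges == 2 * n - 3

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrix_recovered_exactly(self, n):
        rng = np.random.default_rng(17 + n)
        for _ in range(10):
            dm = random_additive_matrix(rng, n)
            tree = neighbor_joining(dm)
            recovered = tips_distance_matrix(tree, dm.labels)
            np.testing.assert_allclose(recovered, dm.d, atol=1e-9)

    def test_four_taxon_topology_matches_least_squares_oracle(self):
        rng = np.random.default_rng(23)
        # oracle: fit branch lengths of all three quartet topologies by
        # least squares on the path-design matrix; best-fit topology wins.
        # topology k pairs leaf 0 with leaf k.
        pairs = list(itertools.combinations(range(4), 2))

        def design(k):
            split = ({0, k}, {1, 2, 3} - {k})
            rows = []
            for i, j in pairs:
                row = [0.0] * 5
                row[i], row[j] = 1.0, 1.0
                if {i, j} not in split:
                    row[4] = 1.0  # the internal edge is crossed
                rows.append(row)
            return np.array(rows)

        for _ in range(10):
            dm = random_additive_matrix(rng, 4)
            y = np.array([dm.d[i, j] for i, j in pairs])
            residuals = {}
            for k in (1, 2, 3):
                X = design(k)
                coef, *_ = np.linalg.lstsq(X, y, rcond=None)
                residuals[k] = float(np.sum((X @ coef - y) ** 2))
            best_partner = dm.labels[min(residuals, key=residuals.get)]

            tree = neighbor_joining(dm)
            # the 4-taxon tree is a trifurcating root with one internal cherry
            internal = next(ch for ch in tree.children if ch.children)
            cherry = {t.name for t in internal.tips()}
            first = dm.labels[0]
            if first in cherry:
                partner = (cherry - {first}).pop()
            else:
                partner = (set(dm.labels) - cherry - {first}).pop()
            assert partner == best_partner

    def test_equal_distance_tie_break_deterministic(self):
        labels = [f"t{i}" for i in range(5)]
        d = np.ones((5, 5)) - np.eye(5)
        dm = DistanceMatrix(labels, d.copy())
        first = to_newick(neighbor_joining(dm))
        second = to_newick(neighbor_joining(DistanceMatrix(labels, d.copy())))
        assert first == second
        # lexicographically-first minimal pair joined first
        tree = neighbor_joining(DistanceMatrix(labels, d.copy()))
        t0 = next(t for t in tree.tips() if t.name == "t0")
        assert {t.name for t in t0.parent.tips()} >= {"t0", "t1"}

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(31)
        dm = random_additive_matrix(rng, 6)
        perm = list(rng.permutation(6))
        labels_p = [dm.labels[i] for i in perm]
        d_p = dm.d[np.ix_(perm, perm)]
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(DistanceMatrix(labels_p, d_p))
        np.testing.assert_allclose(
            tips_distance_matrix(t1, dm.labels),
            tips_distance_matrix(t2, dm.labels),
            atol=1e-9,
        )

    def test_newick_roundtrip(self, tmp_path):
        rng = np.random.default_rng(37)
        dm = random_additive_matrix(rng, 5)
        tree = neighbor_joining(dm)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        np.testing.assert_allclose(
            tips_distance_matrix(back, dm.labels),
            tips_distance_matrix(tree, dm.labels),
            atol=1e-6,
        )


class TestGroupCut:
    def _two_clade_tree(self):
        labels = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i == j:
                    continue
                same = (i < 3) == (j < 3)
                d[i, j] = 0.2 if same else 2.0
        return neighbor_joining(DistanceMatrix(labels, d)), labels

    def test_k1_single_group(self):
        tree, labels = self._two_clade_tree()
        assert group_cut(tree, 1) == [set(labels)]

    def test_planted_clades_recovered_at_k2(self):
        tree, _ = self._two_clade_tree()
        assert group_cut(tree, 2) == [{"a1", "a2", "a3"}, {"b1", "b2", "b3"}]

    def test_kn_singletons(self):
        tree, labels = self._two_clade_tree()
        groups = group_cut(tree, 6)
        assert groups == [{l} for l in sorted(labels)]

    def test_invalid_k(self):
        tree, _ = self._two_clade_tree()
        with pytest.raises(ValueError):
            group_cut(tree, 0)
        with pytest.raises(ValueError):
            group_cut(tree, 7)

    def test_groups_partition_leaves(self):
        tree, labels = self._two_clade_tree()
        for k in range(1, 7):
            groups = group_cut(tree, k)
            assert sum(len(g) for g in groups) == 6
            assert set().union(*groups) == set(labels)
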