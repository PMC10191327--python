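import numpy as np
import pandas as pd
import pytest

from caryomorph.distnet import (
    DistanceMatrix,
    SNPMatrix,
    export_newick,
    mahalanobis_groups,
    mantel,
    neighbor_joining,
    read_newick,
    sokal_michener,
)
from caryomorph.morphostats import FeatureMatrix


def _fm(X, y):
    labels = pd.DataFrame({"g": y})
    labels.index = [f"s{i}" for i in range(len(y))]
    return FeatureMatrix(
        values=np.asarray(X, float),
        feature_names=[f"f{j}" for j in range(np.shape(X)[1])],
        labels=labels,
    )


def random_additive_tree(n_leaves, rng):
    """Random unrooted binary tree and its exact path-length metric."""
    import dendropy

    tns = dendropy.TaxonNamespace([f"T{i}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [dendropy.Node(taxon=tns.get_taxon(f"T{i}")) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for pos in (j, i):  # pop larger index first
            child = nodes.pop(pos)
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(parent)
    root = dendropy.Node()
    for child in nodes:
        root.add_child(child)
        child.edge.length = float(rng.uniform(0.1, 2.0))
    tree.seed_node = root
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    labels = [f"T{i}" for i in range(n_leaves)]
    D = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(a + 1, n_leaves):
            D[a, b] = D[b, a] = pdm.distance(
                tns.get_taxon(labels[a]), tns.get_taxon(labels[b])
            )
    return labels, D


class TestDistanceMatrix:
    def test_symmetry_and_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], D=np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], D=np.array([[1.0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], D=np.array([[0, -1.0], [-1, 0]]))


class TestMahalanobis:
    def test_whitened_data_reduces_to_euclidean_of_means(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = rng.normal(size=(2 * n, 2))
        X[n:] += [3.0, -1.0]
        fm = _fm(X, ["a"] * n + ["b"] * n)
        dm = mahalanobis_groups(fm, "g")
        mu_a, mu_b = X[:n].mean(axis=0), X[n:].mean(axis=0)
        assert dm.D[0, 1] == pytest.approx(np.linalg.norm(mu_a - mu_b), rel=0.02)

    def test_duplicate_group_zero_distance(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 3))
        X = np.vstack([base, base, base + 5.0])
        y = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        dm = mahalanobis_groups(_fm(X, y), "g")
        i, j = dm.labels.index("a"), dm.labels.index("b")
        assert dm.D[i, j] == pytest.approx(0.0, abs=1e-9)

    def test_analytic_two_gaussian_value(self):
        """With known covariance S and mean shift d, the distance tends to
        sqrt(d' S^-1 d)."""
        rng = np.random.default_rng(0)
        n = 10_000
        S = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(S)
        d = np.array([1.0, 0.5])
        X = np.vstack([rng.normal(size=(n, 2)) @ L.T,
                       rng.normal(size=(n, 2)) @ L.T + d])
        dm = mahalanobis_groups(_fm(X, ["a"] * n + ["b"] * n), "g")
        expect = float(np.sqrt(d @ np.linalg.solve(S, d)))
        assert dm.D[0, 1] == pytest.approx(expect, rel=0.02)

    def test_singleton_group_rejected_by_name(self):
        X = np.random.default_rng(3).normal(size=(7, 2))
        y = ["a"] * 3 + ["b"] * 3 + ["solo"]
        with pytest.raises(ValueError, match="solo"):
            mahalanobis_groups(_fm(X, y), "g")


class TestNeighborJoining:
    def test_three_taxon_worked_example(self):
        """D_AB=5, D_AC=9, D_BC=10 gives pendant branches (2, 3, 7)."""
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            D=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths == {"A": 2.0, "B": 3.0, "C": 7.0}

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            labels, D = random_additive_tree(4, rng)
            tree = neighbor_joining(DistanceMatrix(labels=labels, D=D))
            back = tree.path_distance_matrix().reorder(labels)
            np.testing.assert_allclose(back.D, D, atol=1e-9)

    def test_star_metric_zero_internal_branches(self):
        n = 5
        D = np.full((n, n), 2.0)
        np.fill_diagonal(D, 0.0)
        labels = [f"L{i}" for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(labels=labels, D=D))
        internal = [
            e.length for e in tree.tree.preorder_edge_iter()
            if e.head_node and not e.head_node.is_leaf() and e.length is not None
        ]
        assert all(abs(l) < 1e-9 for l in internal)

    def test_fewer_than_three_rejected(self):
        dm = DistanceMatrix(labels=["a", "b"], D=np.array([[0, 1.0], [1, 0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_agrees_with_skbio_topology(self):
        """Cross-check against an independent NJ implementation on a noisy
        (non-additive) matrix: same tree topology."""
        import io

        import skbio

        rng = np.random.default_rng(5)
        labels, D = random_additive_tree(7, rng)
        D = D + rng.uniform(0, 0.05, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = neighbor_joining(DistanceMatrix(labels=labels, D=D))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        import dendropy

        tns = ours.tree.taxon_namespace
        theirs = dendropy.Tree.get(
            data=str(sk_tree), schema="newick", taxon_namespace=tns
        )
        ours_topo = ours.tree.clone(depth=1)
        rf = dendropy.calculate.treecompare.symmetric_difference(
            ours_topo, theirs, is_bipartitions_updated=False
        )
        assert rf == 0


class TestSokalMichener:
    def test_identical_and_complementary_rows(self):
        G = np.array([[1, 0, 1, 1], [1, 0, 1, 1], [0, 1, 0, 0]])
        dm = sokal_michener(SNPMatrix(varieties=["a", "b", "c"], genotypes=G))
        assert dm.D[0, 1] == 0.0
        assert dm.D[0, 2] == 1.0

    def test_half_matching_rows(self):
        rng = np.random.default_rng(6)
        g1 = rng.integers(0, 2, 784)
        g2 = g1.copy()
        flip = rng.choice(784, size=392, replace=False)
        g2[flip] = 1 - g2[flip]
        dm = sokal_michener(SNPMatrix(varieties=["a", "b"], genotypes=np.vstack([g1, g2])))
        assert dm.D[0, 1] == pytest.approx(0.5)

    def test_pairwise_deletion_of_missing(self):
        G = np.array([[1, 0, 1, 0], [1, 1, 1, 0]])
        missing = np.zeros_like(G, dtype=bool)
        missing[1, 1] = True  # the only disagreeing marker is masked
        dm = sokal_michener(
            SNPMatrix(varieties=["a", "b"], genotypes=G, missing=missing)
        )
        assert dm.D[0, 1] == 0.0

    def test_no_shared_markers_rejected(self):
        G = np.array([[1, 0], [0, 1]])
        missing = np.array([[False, True], [True, False]])
        with pytest.raises(ValueError, match="shares no"):
            sokal_michener(SNPMatrix(varieties=["a", "b"], genotypes=G, missing=missing))

    def test_metric_properties_exhaustive_small(self):
        """Symmetry, identity and triangle inequality over all binary
        genotype triples of 3 markers."""
        from itertools import product

        rows = list(product([0, 1], repeat=3))
        for g1 in rows[:4]:
            for g2 in rows:
                for g3 in rows:
                    G = np.array([g1, g2, g3])
                    dm = sokal_michener(
                        SNPMatrix(varieties=["a", "b", "c"], genotypes=G)
                    )
                    D = dm.D
                    assert D[0, 1] == D[1, 0]
                    if g1 == tuple(g2):
                        assert D[0, 1] == 0.0
                    assert D[0, 2] <= D[0, 1] + D[1, 2] + 1e-12


class TestMantel:
    def _dm(self, D, labels=None, kind="euclidean"):
        labels = labels or [f"v{i}" for i in range(len(D))]
        return DistanceMatrix(labels=labels, D=np.asarray(D, float), kind=kind)

    def _random_dm(self, n, rng):
        X = rng.normal(size=(n, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        return self._dm(D)

    def test_self_comparison(self):
        rng = np.random.default_rng(7)
        d1 = self._random_dm(10, rng)
        res = mantel(d1, d1, B=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(8)
        d1 = self._random_dm(9, rng)
        d2 = self._dm(2.5 * d1.D + 1.0 - np.diag(np.full(9, 1.0)))
        res = mantel(d1, d2, B=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        d1 = self._random_dm(6, rng)
        d2 = self._random_dm(6, rng)
        d2.labels = [f"w{i}" for i in range(6)]
        with pytest.raises(ValueError, match="label sets"):
            mantel(d1, d2)

    def test_label_reordering_is_automatic(self):
        rng = np.random.default_rng(10)
        d1 = self._random_dm(8, rng)
        perm = rng.permutation(8)
        d2 = DistanceMatrix(
            labels=[d1.labels[i] for i in perm], D=d1.D[np.ix_(perm, perm)]
        )
        res = mantel(d1, d2, B=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        D = np.full((5, 5), 3.0)
        np.fill_diagonal(D, 0)
        rng = np.random.default_rng(11)
        with pytest.raises(ValueError, match="constant"):
            mantel(self._dm(D), self._random_dm(5, rng))

    def test_agrees_with_skbio_r(self):
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(12)
        d1, d2 = self._random_dm(12, rng), self._random_dm(12, rng)
        res = mantel(d1, d2, B=99, seed=0)
        r_sk, _, _ = sk_mantel(
            d1.D, d2.D, method="pearson", permutations=0
        )
        assert res.statistic == pytest.approx(float(r_sk), abs=1e-10)


class TestNewick:
    def _tree(self):
        dm = DistanceMatrix(
            labels=["A", "B", "C"],
            D=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]]),
        )
        return neighbor_joining(dm)

    def test_three_taxon_newick_string(self, tmp_path):
        tree = self._tree()
        export_newick(tree, tmp_path / "t.nwk")
        text = (tmp_path / "t.nwk").read_text()
        for tok in ("A:2", "B:3", "C:7"):
            assert tok in text.replace(".0", "")

    def test_round_trip_isomorphic(self, tmp_path):
        import dendropy

        tree = self._tree()
        export_newick(tree, tmp_path / "t.nwk")
        back = read_newick(tmp_path / "t.nwk")
        lengths = sorted(
            leaf.edge.length for leaf in back.leaf_node_iter()
        )
        assert lengths == [2.0, 3.0, 7.0]

    def test_labels_with_spaces_quoted(self, tmp_path):
        dm = DistanceMatrix(
            labels=["two row", "six row", "naked type"],
            D=np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0.0]]),
        )
        tree = neighbor_joining(dm)
        export_newick(tree, tmp_path / "s.nwk")
        back = read_newick(tmp_path / "s.nwk")
        labels = {l.taxon.label for l in back.leaf_node_iter()}
        assert labels == {"two row", "six row", "naked type"}
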