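"""Neighbor joining, bootstrap resampling, and leaf stability."""

import numpy as np
import pytest

from scgenus import (
    CentroidProfile,
    PhyloDistanceMatrix,
    bootstrap_trees,
    centroid_correlation_distance,
    leaf_stability_index,
    neighbor_joining,
    point_estimate_tree,
)


def random_additive_tree(rng, n_tips):
    """Random binary tree topology with positive branch lengths.

    Returns (tip labels, additive distance matrix) where distances are
    path-length sums on the generating tree.
    """
    # start from a 3-tip star, then attach tips by subdividing random edges
    edges = {}  # (u, v) sorted -> length
    center = n_tips  # internal ids start above the tip ids
    for t in range(3):
        edges[(t, center)] = rng.uniform(0.2, 2.0)
    next_id = n_tips + 1
    for t in range(3, n_tips):
        u, v = list(edges)[rng.integers(len(edges))]
        l = edges.pop((u, v))
        mid = next_id
        next_id += 1
        split = rng.uniform(0.2, 0.8)
        edges[tuple(sorted((u, mid)))] = l * split
        edges[tuple(sorted((v, mid)))] = l * (1 - split)
        edges[tuple(sorted((t, mid)))] = rng.uniform(0.2, 2.0)
    # all-pairs path lengths over the tree graph
    adj = {}
    for (u, v), l in edges.items():
        adj.setdefault(u, []).append((v, l))
        adj.setdefault(v, []).append((u, l))
    D = np.zeros((n_tips, n_tips))
    for src in range(n_tips):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, l in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + l
                    stack.append(y)
        for dst in range(n_tips):
            D[src, dst] = dist[dst]
    labels = [f"t{i:02d}" for i in range(n_tips)]
    return labels, D


class TestCorrelationDistance:
    def test_identical_vectors_distance_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        profiles = [CentroidProfile("a", v), CentroidProfile("b", v),
                    CentroidProfile("c", np.array([3.0, 1.0, 2.0]))]
        D = centroid_correlation_distance(profiles)
        assert D.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_vectors_distance_two(self):
        profiles = [CentroidProfile("a", np.array([1.0, 2.0, 3.0])),
                    CentroidProfile("b", np.array([3.0, 2.0, 1.0])),
                    CentroidProfile("c", np.array([1.0, 3.0, 2.0]))]
        D = centroid_correlation_distance(profiles)
        assert D.matrix[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_covariance_formula(self, rng):
        vecs = {lab: rng.normal(size=10) for lab in "abc"}
        D = centroid_correlation_distance(
            [CentroidProfile(l, v) for l, v in vecs.items()]
        )
        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                x, y = vecs[a] - vecs[a].mean(), vecs[b] - vecs[b].mean()
                rho = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert D.matrix[i, j] == pytest.approx(1 - rho, abs=1e-12)

    def test_constant_vector_names_tip(self):
        profiles = [CentroidProfile("flat", np.ones(5)),
                    CentroidProfile("b", np.arange(5.0)),
                    CentroidProfile("c", np.arange(5.0)[::-1])]
        with pytest.raises(ValueError, match="flat"):
            centroid_correlation_distance(profiles)


class TestNeighborJoining:
    @pytest.mark.parametrize("n_tips", [4, 5, 6, 7, 8])
    def test_additive_matrix_reconstructed_exactly(self, n_tips):
        rng = np.random.default_rng(n_tips)
        labels, D = random_additive_tree(rng, n_tips)
        tree = neighbor_joining(PhyloDistanceMatrix(labels, D))
        got = tree.tip_path_lengths().loc[labels, labels].values
        assert np.allclose(got, D, atol=1e-9)

    def test_three_taxa_three_point_formulas(self):
        labels = ["a", "b", "c"]
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = neighbor_joining(PhyloDistanceMatrix(labels, D))
        bl = {tree.tip_labels[c]: l for c, l in tree.children[tree.root]}
        assert bl["a"] == pytest.approx(1.0)
        assert bl["b"] == pytest.approx(2.0)
        assert bl["c"] == pytest.approx(3.0)

    def test_all_zero_distances_give_zero_branches(self):
        D = np.zeros((4, 4))
        tree = neighbor_joining(PhyloDistanceMatrix(list("abcd"), D))
        assert np.allclose(tree.tip_path_lengths().values, 0.0)

    def test_branch_lengths_nonnegative_on_noisy_matrices(self, rng):
        for _ in range(10):
            labels, D = random_additive_tree(rng, 6)
            D = D + rng.normal(scale=0.05, size=D.shape)
            D = np.triu(D, 1)
            D = D + D.T
            tree = neighbor_joining(PhyloDistanceMatrix(labels, D))
            for kids in tree.children.values():
                assert all(l >= 0 for _, l in kids)

    def test_topology_agrees_with_reference_implementation(self, rng):
        """Cross-check against scikit-bio's independent NJ on random matrices."""
        skbio = pytest.importorskip("skbio")

        for trial in range(5):
            labels, D = random_additive_tree(np.random.default_rng(50 + trial), 7)
            D = (D + D.T) / 2  # exact symmetry for skbio's strict check
            mine = neighbor_joining(PhyloDistanceMatrix(labels, D))
            ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
            ref_dist = np.array(
                [[ref.find(a).distance(ref.find(b)) for b in labels] for a in labels]
            )
            assert np.allclose(mine.tip_path_lengths().loc[labels, labels].values,
                               ref_dist, atol=1e-6)

    def test_nan_matrix_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            PhyloDistanceMatrix(list("abc"), D)

    def test_newick_round_trips_through_dendropy(self, rng):
        import dendropy

        labels, D = random_additive_tree(rng, 6)
        tree = neighbor_joining(PhyloDistanceMatrix(labels, D))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set(labels)


class TestBootstrap:
    def cells_for(self, rng, n_tips=5, n_cells=20, dim=10):
        return {
            f"t{i}": rng.normal(loc=rng.normal(scale=3, size=dim), size=(n_cells, dim))
            for i in range(n_tips)
        }

    def test_singleton_cells_make_bootstrap_deterministic(self, rng):
        cells = {f"t{i}": rng.normal(size=(1, 8)) for i in range(5)}
        boots = bootstrap_trees(cells, n_boot=10, seed=0)
        point = point_estimate_tree(cells)
        for tree in boots:
            assert tree.newick() == point.newick()

    def test_same_seed_reproduces_trees(self, rng):
        cells = self.cells_for(rng)
        t1 = bootstrap_trees(cells, n_boot=5, seed=3)
        t2 = bootstrap_trees(cells, n_boot=5, seed=3)
        assert [t.newick() for t in t1] == [t.newick() for t in t2]

    def test_requested_number_of_trees(self, rng):
        cells = self.cells_for(rng)
        assert len(bootstrap_trees(cells, n_boot=37, seed=0)) == 37

    def test_empty_tip_rejected(self, rng):
        cells = self.cells_for(rng)
        cells["empty"] = np.zeros((0, 10))
        with pytest.raises(ValueError, match="empty"):
            bootstrap_trees(cells, n_boot=2, seed=0)


class TestLeafStability:
    def tree_from_newick(self, newick, labels):
        """Build a CellTypeTree by NJ on the path-length matrix of a topology."""
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        D = np.array(
            [[0.0 if a == b else pdm.patristic_distance(taxa[a], taxa[b]) for b in labels]
             for a in labels]
        )
        return neighbor_joining(PhyloDistanceMatrix(labels, D))

    def test_identical_bootstrap_trees_give_lsi_one(self, rng):
        labels = list("abcde")
        tree = self.tree_from_newick("((a:1,b:1):1,(c:1,d:1):1,e:2);", labels)
        lsi = leaf_stability_index([tree] * 100)
        assert all(v == pytest.approx(1.0) for v in lsi.values())

    def test_cycling_resolutions_give_one_third(self):
        labels = list("abcd")
        t1 = self.tree_from_newick("((a:1,b:1):1,c:2,d:2);", labels)
        t2 = self.tree_from_newick("((a:1,c:1):1,b:2,d:2);", labels)
        t3 = self.tree_from_newick("((a:1,d:1):1,b:2,c:2);", labels)
        lsi = leaf_stability_index([t1, t2, t3] * 10)
        assert all(v == pytest.approx(1 / 3, abs=1e-9) for v in lsi.values())

    def test_four_tips_single_quartet_per_tip(self):
        labels = list("abcd")
        t1 = self.tree_from_newick("((a:1,b:1):1,c:2,d:2);", labels)
        t2 = self.tree_from_newick("((a:1,c:1):1,b:2,d:2);", labels)
        lsi = leaf_stability_index([t1, t1, t1, t2])
        assert all(v == pytest.approx(0.75) for v in lsi.values())

    def test_fewer_than_four_tips_rejected(self):
        tree = self.tree_from_newick("(a:1,b:1,c:1);", list("abc"))
        with pytest.raises(ValueError):
            leaf_stability_index([tree])

    def test_quartet_subsampling_close_to_exhaustive(self, rng):
        cells = {
            f"t{i}": rng.normal(loc=rng.normal(scale=3, size=8), size=(15, 8))
            for i in range(8)
        }
        boots = bootstrap_trees(cells, n_boot=30, seed=0)
        full = leaf_stability_index(boots, max_quartets_per_tip=10**6)
        sub = leaf_stability_index(boots, max_quartets_per_tip=20, seed=1)
        for lab in full:
            assert abs(full[lab] - sub[lab]) < 0.25
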