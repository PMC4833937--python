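import numpy as np
import pytest

from glyfam.phylo import (
    DistanceMatrix,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
)


def random_additive_tree(rng, n: int) -> PhyloTree:
    """Random unrooted binary tree with strictly positive branch lengths."""
    pool = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 2)))
            for i in range(n)]
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), 2, replace=False))
        a, b = pool[int(i)], pool[int(j)]
        parent = TreeNode(length=float(rng.uniform(0.1, 2)), children=[a, b])
        pool = [x for k, x in enumerate(pool) if k not in (int(i), int(j))]
        pool.append(parent)
    return PhyloTree(TreeNode(children=pool))


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix({"a": "MKVL", "b": "MKVL"})
        assert dm.d[0, 1] == 0.0

    def test_quarter_distance(self):
        dm = p_distance_matrix({"a": "AAAA", "b": "AAAT"})
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_pairwise_gap_deletion(self):
        dm = p_distance_matrix({"a": "A-AA", "b": "AGAT"})
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_errors(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "A--", "b": "-GG"})

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "AA", "b": "AAA"})


class TestNeighborJoining:
    def test_four_leaf_additive_example(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        # topology AB|CD
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        # branch lengths 1,2,3,4 and internal edge 1, checked via path sums
        pl = tree.path_lengths()
        assert np.allclose(pl.d, d)

    def test_three_leaves_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABC"), d))
        pl = tree.path_lengths()
        assert np.allclose(pl.d, d)

    def test_star_tree_zero_internal_edges(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(
            DistanceMatrix([f"L{i}" for i in range(n)], d)
        )
        pl = tree.path_lengths()
        assert np.allclose(pl.d, d, atol=1e-12)

    def test_fewer_than_three_errors(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
            )

    def test_additive_recovery_property(self):
        """NJ recovers topology and branch lengths exactly on random
        additive matrices (4-12 leaves, 100 trials)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            truth = random_additive_tree(rng, n)
            dm = truth.path_lengths()
            est = neighbor_joining(dm)
            assert est.bipartitions() == truth.bipartitions()
            assert np.abs(est.path_lengths().d - dm.d).max() < 1e-9

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(7)
        truth = random_additive_tree(rng, 6)
        dm = truth.path_lengths()
        perm = rng.permutation(len(dm.labels))
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        t1, t2 = neighbor_joining(dm), neighbor_joining(dm2)
        assert t1.bipartitions() == t2.bipartitions()

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check of the NJ machinery on a non-additive
        matrix: same topology as skbio.tree.nj."""
        import skbio

        rng = np.random.default_rng(3)
        n = 7
        noise = rng.uniform(0, 0.05, (n, n))
        truth = random_additive_tree(rng, n)
        d = truth.path_lengths().d + noise + noise.T
        np.fill_diagonal(d, 0.0)
        labels = truth.path_lengths().labels
        ours = neighbor_joining(DistanceMatrix(labels, d))

        sk_tree = skbio.tree.nj(
            skbio.DistanceMatrix(d, ids=labels)
        )
        sk_parts = set()
        all_leaves = frozenset(labels)
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                sk_parts.add(
                    min(below, all_leaves - below,
                        key=lambda s: (len(s), sorted(s)))
                )
        assert ours.bipartitions() == sk_parts

    def test_newick_round_trip_via_dendropy(self):
        import dendropy

        rng = np.random.default_rng(9)
        tree = neighbor_joining(random_additive_tree(rng, 6).path_lengths())
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == set(
            tree.leaf_names
        )


def strong_signal_alignment() -> dict[str, str]:
    """Two clearly separated leaf clusters with long shared signal."""
    block_a = "AAAAAAAAAA" * 4
    block_b = "TTTTTTTTTT" * 4
    return {
        "a1": block_a + "CD",
        "a2": block_a + "CE",
        "b1": block_b + "CD",
        "b2": block_b + "CF",
        "out": "GGGGGGGGGG" * 4 + "CD",
    }


class TestBootstrap:
    def test_strong_split_high_support(self):
        tree = bootstrap_support(strong_signal_alignment(), n_reps=100, seed=1)
        supports = {
            frozenset(part): None for part in tree.bipartitions()
        }
        # find the a1a2 bipartition's support on the tree
        def find(node):
            vals = []
            if not node.is_leaf:
                leaves = frozenset(l.name for l in node.leaves())
                if node.support is not None:
                    vals.append((leaves, node.support))
                for c in node.children:
                    vals.extend(find(c))
            return vals

        found = dict(find(tree.root))
        a_split = frozenset({"a1", "a2"})
        assert found.get(a_split, 0) >= 95

    def test_single_replicate_support_binary(self):
        tree = bootstrap_support(strong_signal_alignment(), n_reps=1, seed=0)
        sups = [
            n.support
            for n in _internal_nodes(tree.root)
            if n.support is not None
        ]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_seed_determinism(self):
        t1 = bootstrap_support(strong_signal_alignment(), n_reps=30, seed=5)
        t2 = bootstrap_support(strong_signal_alignment(), n_reps=30, seed=5)
        assert t1.to_newick() == t2.to_newick()


def _internal_nodes(node):
    if not node.is_leaf:
        yield node
        for c in node.children:
            yield from _internal_nodes(c)
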