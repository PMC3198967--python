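"""Neighbor joining, bootstrap supports, Fitch and branch-and-bound parsimony."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from oracles import (
    bruteforce_parsimony,
    edge_bipartitions,
    enumerate_topologies,
    least_squares_fit,
)
from ychap import (
    Alignment,
    bipartitions,
    bootstrap_support,
    fitch_length,
    mp_search,
    nj_tree,
    tree_distance_matrix,
)


def _random_additive_matrix(n, rng):
    """Distance matrix generated from a random topology with random
    positive branch lengths; returns (matrix, generating splits)."""
    edges = enumerate_topologies(n)[rng.integers(0, len(enumerate_topologies(n)))]
    lengths = {tuple(sorted(e)): rng.uniform(0.5, 3.0) for e in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    dm = np.zeros((n, n))
    for a in range(n):
        stack = [(a, -1, 0.0)]
        while stack:
            node, parent, dist = stack.pop()
            if node < n:
                dm[a, node] = dist
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node, dist + lengths[tuple(sorted((node, nb)))]))
    dm = (dm + dm.T) / 2  # exact symmetry despite float summation order
    return dm, edge_bipartitions(edges, n)


def _named_splits(splits, ids):
    return {frozenset(ids[i] for i in s) for s in splits}


class TestNeighborJoining:
    def test_three_taxa_exact(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=list("abc"))
        tree = nj_tree(dm)
        got = {t.name: t.length for t in tree.tips()}
        assert got == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_additive_four_taxon_recovery(self):
        # ((A:1,B:2):1,(C:3,D:4)) pairwise path lengths
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], ids=list("ABCD")
        )
        tree = nj_tree(dm)
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        recovered = tree_distance_matrix(tree)
        for a in "ABCD":
            for b in "ABCD":
                assert recovered[a, b] == pytest.approx(dm[a, b], abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_six_taxon_additive_matches_exhaustive_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        dm, true_splits = _random_additive_matrix(n, rng)
        ids = [f"t{i}" for i in range(n)]
        tree = nj_tree(DistanceMatrix(dm, ids=ids))
        # oracle: best topology over all 105 by nonneg least squares
        best_sse, best_splits = None, None
        for edges in enumerate_topologies(n):
            sse = least_squares_fit(edges, n, dm)
            if best_sse is None or sse < best_sse:
                best_sse, best_splits = sse, edge_bipartitions(edges, n)
        assert best_splits == true_splits
        assert bipartitions(tree) == _named_splits(true_splits, ids)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_path_lengths_reproduce_additive_input(self, seed):
        rng = np.random.default_rng(seed)
        dm, _ = _random_additive_matrix(5, rng)
        ids = [f"t{i}" for i in range(5)]
        tree = nj_tree(DistanceMatrix(dm, ids=ids))
        recovered = tree_distance_matrix(tree)
        for i in range(5):
            for j in range(5):
                assert recovered[ids[i], ids[j]] == pytest.approx(dm[i, j], abs=1e-9)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(7)
        dm, _ = _random_additive_matrix(6, rng)
        ids = [f"t{i}" for i in range(6)]
        t1 = nj_tree(DistanceMatrix(dm, ids=ids))
        perm = [3, 0, 5, 1, 4, 2]
        t2 = nj_tree(DistanceMatrix(dm[np.ix_(perm, perm)], ids=[ids[i] for i in perm]))
        assert bipartitions(t1) == bipartitions(t2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


def _split_alignment(n_support=20, n_noise=0, n_const=80, seed=0):
    """Four taxa with n_support columns supporting the (a1,a2)|(b1,b2)
    split, constant padding to keep divergence below saturation, and
    optional random noise columns."""
    rng = np.random.default_rng(seed)
    cols = [("A", "A", "C", "C")] * n_support + [("G", "G", "G", "G")] * n_const
    for _ in range(n_noise):
        cols.append(tuple(rng.choice(list("ACGT"), 4)))
    rows = ["".join(c[i] for c in cols) for i in range(4)]
    return Alignment(("a1", "a2", "b1", "b2"), tuple(rows))


class TestBootstrap:
    def test_strong_split_highly_supported(self):
        aln = _split_alignment(n_support=20, n_noise=5, seed=1)
        _, supports = bootstrap_support(aln, n_reps=200, seed=11)
        split = frozenset({"b1", "b2"})
        assert supports[split] >= 95.0

    def test_single_replicate_supports_are_all_or_nothing(self):
        aln = _split_alignment(n_support=5, n_noise=3, seed=2)
        _, supports = bootstrap_support(aln, n_reps=1, seed=3)
        assert set(supports.values()) <= {0.0, 100.0}

    def test_seed_reproducibility(self):
        aln = _split_alignment(n_support=8, n_noise=6, seed=4)
        _, s1 = bootstrap_support(aln, n_reps=50, seed=99)
        _, s2 = bootstrap_support(aln, n_reps=50, seed=99)
        assert s1 == s2

    def test_taxon_order_invariance(self):
        aln = _split_alignment(n_support=8, n_noise=6, seed=5)
        shuffled = aln.subset(["b2", "a1", "b1", "a2"])
        _, s1 = bootstrap_support(aln, n_reps=40, seed=5)
        _, s2 = bootstrap_support(shuffled, n_reps=40, seed=5)
        assert s1 == s2

    def test_supports_written_on_tree(self):
        aln = _split_alignment(n_support=20, seed=6)
        tree, supports = bootstrap_support(aln, n_reps=20, seed=7)
        labels = {n.name for n in tree.traverse() if not n.is_tip() and n.name}
        assert labels == {f"{v:.0f}" for v in supports.values()}


def _columns_for_oracle(aln):
    full = frozenset("ACGT")
    lookup = {b: frozenset(b) for b in "ACGT"}
    return [
        tuple(lookup.get(seq[j], full) for seq in aln.seqs) for j in range(aln.length)
    ]


class TestFitch:
    def test_constant_alignment_zero(self):
        aln = Alignment(("a", "b", "c", "d"), ("AAA",) * 4)
        trees, _ = mp_search(aln)
        assert fitch_length(trees[0], aln) == 0

    def test_textbook_single_column(self):
        aln = Alignment(("t1", "t2", "t3", "t4"), ("A", "A", "C", "C"))
        trees, length = mp_search(aln)
        assert length == 1
        assert fitch_length(trees[0], aln) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_ancestral_assignment(self, seed):
        rng = np.random.default_rng(seed)
        n, L = 5, 12
        rows = ["".join(rng.choice(list("ACGTN"), L)) for _ in range(n)]
        aln = Alignment(tuple(f"t{i}" for i in range(n)), tuple(rows))
        cols = _columns_for_oracle(aln)
        for edges in enumerate_topologies(n)[::5]:
            from skbio import TreeNode

            # rebuild a TreeNode from the edge list, independently
            adj = {}
            for u, v in edges:
                adj.setdefault(u, []).append(v)
                adj.setdefault(v, []).append(u)

            def build(node, parent):
                if node < n:
                    return TreeNode(name=f"t{node}")
                return TreeNode(children=[build(x, node) for x in adj[node] if x != parent])

            root = adj[0][0]
            tree = TreeNode(
                children=[TreeNode(name="t0")] + [build(x, root) for x in adj[root] if x != 0]
            )
            assert fitch_length(tree, aln) == bruteforce_parsimony(edges, n, cols)

    def test_rerooting_invariance(self):
        rng = np.random.default_rng(9)
        rows = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(5)]
        aln = Alignment(tuple(f"t{i}" for i in range(5)), tuple(rows))
        trees, length = mp_search(aln)
        tree = trees[0]
        tip = list(tree.tips())[2]
        rerooted = tree.root_at(tip.parent)
        assert fitch_length(rerooted, aln) == fitch_length(tree, aln) == length

    def test_label_mismatch_rejected(self):
        aln = Alignment(("a", "b", "c", "d"), ("AC", "AC", "GT", "GT"))
        trees, _ = mp_search(aln)
        other = Alignment(("a", "b", "c", "x"), ("AC", "AC", "GT", "GT"))
        with pytest.raises(ValueError, match="match"):
            fitch_length(trees[0], other)


class TestBranchAndBound:
    def test_informative_column_determines_split(self):
        aln = Alignment(("t1", "t2", "t3", "t4"), ("AAC", "AAC", "ACA", "ACA"))
        trees, length = mp_search(aln)
        assert length == 2
        assert len(trees) == 1
        assert bipartitions(trees[0]) == {frozenset({"t3", "t4"})}

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2)])
    def test_equals_exhaustive_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(n)]
        aln = Alignment(tuple(f"t{i}" for i in range(n)), tuple(rows))
        cols = _columns_for_oracle(aln)
        scored = [
            (bruteforce_parsimony(edges, n, cols), edges) for edges in enumerate_topologies(n)
        ]
        best = min(s for s, _ in scored)
        best_splits = {
            frozenset(frozenset(f"t{i}" for i in s) for s in edge_bipartitions(e, n))
            for score, e in scored
            if score == best
        }
        trees, length = mp_search(aln)
        assert length == best
        assert {frozenset(bipartitions(t)) for t in trees} == best_splits

    def test_too_many_taxa_rejected(self):
        aln = Alignment(tuple(f"t{i}" for i in range(8)), ("A",) * 8)
        with pytest.raises(ValueError, match="max_taxa"):
            mp_search(aln, max_taxa=7)
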