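"""Distance computation, neighbor joining, bootstrap, branch assignment."""

import numpy as np
import pytest

from retrodiff.cohort_share import ANCESTOR, MergedLocus, PresenceMatrix
from retrodiff.phylo import (
    DistanceMatrix,
    RootedTree,
    assign_loci_to_branches,
    bootstrap_support,
    neighbor_joining,
    p_distance_matrix,
)


def _matrix(rows, samples):
    values = np.array(rows, dtype=bool)
    loci = [
        MergedLocus(f"L{i}", "chr1", 1000 * i, 1000 * i, "insertion", "SINEC",
                    {s for s, v in zip(samples, row) if v})
        for i, row in enumerate(values)
    ]
    return PresenceMatrix(loci, list(samples), values)


def _random_tree_distances(rng, n):
    """A random binary topology with positive lengths; returns (labels, D,
    bipartitions) computed by brute-force path sums."""
    labels = [f"t{i}" for i in range(n)]
    nodes = {i: None for i in range(n)}
    import itertools

    next_id = n
    edges = {}
    active = list(range(n))
    while len(active) > 2:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[int(min(i, j))], active[int(max(i, j))]
        u = next_id
        next_id += 1
        edges[(u, a)] = float(rng.uniform(0.05, 1.0))
        edges[(u, b)] = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x not in (a, b)] + [u]
    edges[tuple(sorted(active))] = float(rng.uniform(0.05, 1.0))
    adj = {}
    for (x, y), l in edges.items():
        adj.setdefault(x, []).append((y, l))
        adj.setdefault(y, []).append((x, l))

    def dist(a, b):
        stack = [(a, -1, 0.0)]
        while stack:
            node, parent, d = stack.pop()
            if node == b:
                return d
            for m, l in adj[node]:
                if m != parent:
                    stack.append((m, node, d + l))
        raise AssertionError

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(i, j)

    def leafset(x, parent):
        if x < n:
            return {labels[x]}
        out = set()
        for m, _ in adj[x]:
            if m != parent:
                out |= leafset(m, x)
        return out

    bips = set()
    for (x, y) in edges:
        side = frozenset(leafset(y, x))
        if 1 < len(side) < n - 1:
            bips.add(min(side, frozenset(labels) - side, key=sorted))
    return labels, D, bips


class TestPDistance:
    def test_identical_columns_have_zero_distance(self):
        m = _matrix([[1, 1, 0], [1, 1, 0], [0, 0, 0], [1, 1, 0]][:2] + [[1, 1, 0]],
                    ["A", "B", ANCESTOR])
        d = p_distance_matrix(m)
        assert d.values[0, 1] == 0 and d.values[0, 0] == 0

    def test_hand_counted_proportion(self):
        # A and B differ at 2 of 8 loci
        rows = [[1, 0, 0], [0, 1, 0]] + [[1, 1, 0]] * 6
        m = _matrix(rows, ["A", "B", ANCESTOR])
        d = p_distance_matrix(m)
        assert d.values[0, 1] == pytest.approx(2 / 8)

    def test_ancestor_distance_is_presence_fraction(self):
        values = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 0], [1, 1, 0]], dtype=bool)
        loci = [MergedLocus(f"L{i}", "chr1", i, i, "insertion", "SINEC", {"A"})
                for i in range(4)]
        m = PresenceMatrix(loci, ["A", "B", ANCESTOR], values)
        d = p_distance_matrix(m)
        assert d.values[0, 2] == pytest.approx(3 / 4)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        t = neighbor_joining(DistanceMatrix(["a", "b", "c"], D))
        lengths = {t.labels[n]: l for n in t.leaves for _, l in [t.adjacency[n][0]]}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrices_recovered_exactly(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(10):
            labels, D, true_bips = _random_tree_distances(rng, n)
            tree = neighbor_joining(DistanceMatrix(labels, D))
            got = set(tree.bipartitions().values())
            canon = {min(b, frozenset(labels) - b, key=sorted) for b in got}
            assert canon == true_bips
            # additivity: the reconstructed tree reproduces every pairwise
            # distance
            for i in range(n):
                for j in range(i + 1, n):
                    assert _tree_distance(tree, labels[i], labels[j]) == pytest.approx(D[i, j])

    def test_agrees_with_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(42)
        labels, D, true_bips = _random_tree_distances(rng, 6)
        ours = neighbor_joining(DistanceMatrix(labels, D))
        theirs = nj(SkDM(D, ids=labels))
        their_bips = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(labels) - 1:
                their_bips.add(min(side, frozenset(labels) - side, key=sorted))
        our_bips = {
            min(b, frozenset(labels) - b, key=sorted)
            for b in ours.bipartitions().values()
        }
        assert our_bips == their_bips

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def _tree_distance(tree, a, b):
    na, nb = tree.leaf_node(a), tree.leaf_node(b)
    stack = [(na, -1, 0.0)]
    while stack:
        node, parent, d = stack.pop()
        if node == nb:
            return d
        for m, l in tree.adjacency[node]:
            if m != parent:
                stack.append((m, node, d + l))
    raise AssertionError


class TestBootstrap:
    def _perfect_matrix(self):
        samples = ["A", "B", "C", "D", ANCESTOR]
        rows = []
        for present, k in [({"A"}, 12), ({"B"}, 11), ({"C"}, 13), ({"D"}, 10),
                           ({"A", "B"}, 15), ({"A", "B", "C"}, 14)]:
            for _ in range(k):
                rows.append([s in present for s in samples])
        values = np.array(rows, dtype=bool)
        loci = [MergedLocus(f"L{i}", "chr1", i, i, "insertion", "SINEC", set())
                for i in range(len(rows))]
        return PresenceMatrix(loci, samples, values)

    def test_conflict_free_matrix_gives_full_support(self):
        tree, support = bootstrap_support(self._perfect_matrix(), replicates=200, seed=1)
        assert support and all(v == 100.0 for v in support.values())

    def test_deterministic_under_seed(self):
        m = self._perfect_matrix()
        _, s1 = bootstrap_support(m, replicates=10, seed=5)
        _, s2 = bootstrap_support(m, replicates=10, seed=5)
        assert s1 == s2


class TestBranchAssignment:
    def test_singletons_and_clades_assigned_non_conforming_tallied(self):
        m = self._assignment_matrix()
        tree, _ = bootstrap_support(m, replicates=10, seed=0)
        rooted = RootedTree.from_unrooted(tree, ANCESTOR)
        out = assign_loci_to_branches(m, rooted)
        assert out["branch_counts"][frozenset({"A"})] == 12
        assert out["branch_counts"][frozenset({"A", "B"})] == 15
        # the {A, C} pattern conflicts with the (A,B) clade: non-conforming
        assert out["non_conforming"][frozenset({"A", "C"})] == 3
        assert out["fit"] + sum(out["non_conforming"].values()) == out["total"]

    def _assignment_matrix(self):
        samples = ["A", "B", "C", "D", ANCESTOR]
        rows = []
        for present, k in [({"A"}, 12), ({"B"}, 11), ({"C"}, 13), ({"D"}, 10),
                           ({"A", "B"}, 15), ({"A", "B", "C"}, 14),
                           ({"A", "C"}, 3)]:
            for _ in range(k):
                rows.append([s in present for s in samples])
        values = np.array(rows, dtype=bool)
        loci = [MergedLocus(f"L{i}", "chr1", i, i, "insertion", "SINEC", set())
                for i in range(len(rows))]
        return PresenceMatrix(loci, samples, values)
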