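"""Presence/absence phylogenetics: p-distance, neighbor joining, bootstrap.

Loci are two-state characters; the p-distance between two assemblies is
simply the proportion of loci at which their presence states differ (no
correction for unobservable characters). The synthetic all-absent
ancestor participates as an ordinary taxon and roots the tree. Trees are
built with the classic Saitou-Nei neighbor-joining agglomeration;
bootstrap support for each internal edge of the full-data tree is the
percentage of locus-resampled replicates containing the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .cohort_share import ANCESTOR, PresenceMatrix, round_percent


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def p_distance_matrix(matrix: PresenceMatrix) -> DistanceMatrix:
    X = matrix.values.astype(np.uint8)
    n_loci = X.shape[0]
    if n_loci == 0:
        raise ValueError("empty presence matrix")
    # differing loci between columns i and j
    diff = (X.T @ (1 - X)) + ((1 - X).T @ X)
    return DistanceMatrix(list(matrix.samples), diff.astype(float) / n_loci)


# ---------------------------------------------------------------------------
# unrooted trees as adjacency maps


@dataclass
class Tree:
    """Unrooted tree: nodes are ints, leaves carry labels."""

    adjacency: Dict[int, List[Tuple[int, float]]] = field(default_factory=dict)
    labels: Dict[int, str] = field(default_factory=dict)

    def add_edge(self, a: int, b: int, length: float) -> None:
        self.adjacency.setdefault(a, []).append((b, length))
        self.adjacency.setdefault(b, []).append((a, length))

    @property
    def leaves(self) -> List[int]:
        return sorted(self.labels)

    def leaf_node(self, label: str) -> int:
        for n, lab in self.labels.items():
            if lab == label:
                return n
        raise KeyError(label)

    def bipartitions(self) -> Dict[Tuple[int, int], FrozenSet[str]]:
        """Internal edge -> canonical side (the side not containing the
        lexicographically smallest leaf label)."""
        ref = min(self.labels.values())
        out: Dict[Tuple[int, int], FrozenSet[str]] = {}
        for a in self.adjacency:
            for b, _ in self.adjacency[a]:
                if a >= b:
                    continue
                side = self._leafset_beyond(a, b)
                other = frozenset(self.labels.values()) - side
                if len(side) < 2 or len(other) < 2:
                    continue  # trivial split
                out[(a, b)] = side if ref not in side else other
        return out

    def _leafset_beyond(self, a: int, b: int) -> FrozenSet[str]:
        """Labels reachable from ``b`` without crossing edge (a, b)."""
        seen = {a, b}
        stack = [b]
        labels: Set[str] = set()
        while stack:
            n = stack.pop()
            if n in self.labels:
                labels.add(self.labels[n])
            for m, _ in self.adjacency[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(labels)

    def newick(self, root_label: Optional[str] = None, support: Optional[Dict[FrozenSet[str], float]] = None) -> str:
        root = self.leaf_node(root_label) if root_label else self.leaves[0]
        start, length = self.adjacency[root][0]

        def rec(node: int, parent: int) -> str:
            children = [(m, l) for m, l in self.adjacency[node] if m != parent]
            if not children:
                return f"{self.labels[node]}"
            parts = [f"{rec(m, node)}:{l:.6g}" for m, l in children]
            label = ""
            if support is not None:
                side = self._leafset_beyond(parent, node)
                ref = min(self.labels.values())
                full = frozenset(self.labels.values())
                key = side if ref not in side else full - side
                if key in support:
                    label = f"{support[key]:g}"
            return "(" + ",".join(parts) + ")" + label

        body = rec(start, root)
        return f"({self.labels[root]}:{length:.6g},{body});"


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei agglomeration with deterministic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit shifted
    to the sister edge so that the pair's summed length is preserved.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = d.values.astype(float).copy()
    active = list(range(n))
    tree = Tree()
    for i, lab in enumerate(d.labels):
        tree.labels[i] = lab
        tree.adjacency.setdefault(i, [])
    next_node = n
    # index into D for each active node
    pos = {i: i for i in active}
    while len(active) > 3:
        m = len(active)
        idx = [pos[a] for a in active]
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                key = (Q[i, j], i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        a, b = active[i], active[j]
        dij = sub[i, j]
        la = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lb = dij - la
        la, lb = _clamp_pair(la, lb)
        u = next_node
        next_node += 1
        tree.add_edge(u, a, la)
        tree.add_edge(u, b, lb)
        # distances from the new node
        newd = 0.5 * (sub[i, :] + sub[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        pos[u] = D.shape[0] - 1
        for k, c in enumerate(active):
            if c in (a, b):
                continue
            D[pos[u], pos[c]] = D[pos[c], pos[u]] = newd[k]
        active = [c for c in active if c not in (a, b)] + [u]
    # terminal 3-star
    a, b, c = active
    ia, ib, ic = pos[a], pos[b], pos[c]
    dab, dac, dbc = D[ia, ib], D[ia, ic], D[ib, ic]
    u = next_node
    tree.add_edge(u, a, max(0.0, 0.5 * (dab + dac - dbc)))
    tree.add_edge(u, b, max(0.0, 0.5 * (dab + dbc - dac)))
    tree.add_edge(u, c, max(0.0, 0.5 * (dac + dbc - dab)))
    return tree


def _clamp_pair(la: float, lb: float) -> Tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la += lb
        lb = 0.0
    return max(la, 0.0), max(lb, 0.0)


def bootstrap_support(
    matrix: PresenceMatrix, replicates: int = 1000, seed: int = 0
) -> Tuple[Tree, Dict[FrozenSet[str], float]]:
    """Full-data NJ tree plus per-bipartition bootstrap percentages.

    Loci are resampled with replacement; each replicate tree's non-trivial
    bipartitions are tallied and the full-data tree's internal edges are
    annotated with the percentage of replicates containing them.
    """
    tree = neighbor_joining(p_distance_matrix(matrix))
    target = set(tree.bipartitions().values())
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_loci = matrix.values.shape[0]
    X = matrix.values
    for _ in range(replicates):
        take = rng.integers(0, n_loci, size=n_loci)
        sub = PresenceMatrix.__new__(PresenceMatrix)
        sub.loci = matrix.loci
        sub.samples = matrix.samples
        sub.values = X[take]
        rep_tree = neighbor_joining(p_distance_matrix(sub))
        seen = set(rep_tree.bipartitions().values())
        for bp in target:
            if bp in seen:
                counts[bp] += 1
    support = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    return tree, support


# ---------------------------------------------------------------------------
# rooted view and branch assignment


@dataclass
class RootedTree:
    """The NJ tree rooted on the ancestor leaf; edges keyed by the leaf set
    below them (assembly samples only)."""

    tree: Tree
    root_label: str
    clades: Dict[Tuple[int, int], FrozenSet[str]] = field(default_factory=dict)

    @classmethod
    def from_unrooted(cls, tree: Tree, root_label: str = ANCESTOR) -> "RootedTree":
        root_leaf = tree.leaf_node(root_label)
        clades: Dict[Tuple[int, int], FrozenSet[str]] = {}

        def walk(node: int, parent: int) -> FrozenSet[str]:
            below: Set[str] = set()
            if node in tree.labels and tree.labels[node] != root_label:
                below.add(tree.labels[node])
            for m, _ in tree.adjacency[node]:
                if m != parent:
                    below |= walk(m, node)
            clades[(parent, node)] = frozenset(below)
            return frozenset(below)

        start = tree.adjacency[root_leaf][0][0]
        walk(start, root_leaf)
        return cls(tree=tree, root_label=root_label, clades=clades)

    def clade_sets(self) -> Set[FrozenSet[str]]:
        return {c for c in self.clades.values() if c}


def assign_loci_to_branches(matrix: PresenceMatrix, rooted: RootedTree):
    """Map each locus to the branch whose descendant leaf set equals its
    presence pattern; tally non-conforming patterns otherwise."""
    samples = matrix.assembly_samples
    idx = [matrix.samples.index(s) for s in samples]
    clade_lookup: Dict[FrozenSet[str], Tuple[int, int]] = {}
    for edge, clade in rooted.clades.items():
        if clade:
            clade_lookup.setdefault(clade, edge)
    branch_counts: Dict[FrozenSet[str], int] = {c: 0 for c in clade_lookup}
    non_conforming: Dict[FrozenSet[str], int] = {}
    fit = 0
    for row in matrix.values:
        present = frozenset(s for s, i in zip(samples, idx) if row[i])
        if present in clade_lookup:
            branch_counts[present] += 1
            fit += 1
        else:
            non_conforming[present] = non_conforming.get(present, 0) + 1
    total = matrix.values.shape[0]
    return {
        "branch_counts": branch_counts,
        "non_conforming": non_conforming,
        "fit": fit,
        "total": total,
        "fit_percent": round_percent(fit, total),
    }
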