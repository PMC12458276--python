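"""Shared test utilities: truth bookkeeping and per-base brute-force oracles."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple


def expected_pair_truth(bundle, sample: str, target: Optional[str] = None):
    """Truth records dimorphic between ``sample`` and ``target``; yields
    ``(record, present_in_sample)`` pairs."""
    target = target or bundle.outgroup
    s_ids = {e.event_id for e in bundle.events_by_leaf[sample]}
    t_ids = {e.event_id for e in bundle.events_by_leaf[target]}
    return [
        (t, t.event_id in s_ids)
        for t in bundle.truth
        if (t.event_id in s_ids) != (t.event_id in t_ids)
    ]


def find_locus(bundle, loci, truth, in_sample: bool, sample: str, target: str):
    """The pipeline locus matching one truth record, by exact breakpoint."""
    if in_sample:
        pos = bundle.maps[target][truth.chrom].project(truth.eff_site)
        matches = [
            l
            for l in loci
            if l.kind == "insertion"
            and l.target_chrom == truth.chrom
            and l.target_start == pos
        ]
    else:
        pos = bundle.maps[sample][truth.chrom].project(truth.eff_site)
        matches = [
            l
            for l in loci
            if l.kind == "deletion"
            and l.query_chrom == truth.chrom
            and l.query_start == pos
        ]
    return matches[0] if len(matches) == 1 else None


def tree_clades(tree: dict) -> List[frozenset]:
    """Leaf sets below every internal (non-root) node of a simulation tree."""
    out: List[frozenset] = []

    def leaves(node):
        if not node.get("children"):
            return [node["name"]]
        acc = []
        for c in node["children"]:
            acc.extend(leaves(c))
        return acc

    def walk(node, is_root):
        if node.get("children") and not is_root:
            out.append(frozenset(leaves(node)))
        for c in node.get("children", []):
            walk(c, False)

    walk(tree, True)
    return out


# ---------------------------------------------------------------------------
# per-base brute-force oracles


def brute_within(query: Tuple[int, int], ivs: Sequence[Tuple[int, int]], w: int) -> bool:
    """Closest-edge distance <= w (0 when overlapping), checked naively."""
    qs, qe = query
    for s, e in ivs:
        if qs < e and qe > s:
            return True
        d = s - qe if s >= qe else qs - e
        if d <= w:
            return True
    return False


def brute_coverage(length: int, ivs: Sequence[Tuple[int, int]]) -> List[bool]:
    cov = [False] * length
    for s, e in ivs:
        for i in range(max(0, s), min(length, e)):
            cov[i] = True
    return cov


def mask_to_intervals(mask: Sequence[bool]) -> List[Tuple[int, int]]:
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def brute_merge_clusters(points: Sequence[Tuple[int, int]], gap: int) -> List[List[int]]:
    """Single-linkage clustering of intervals by closest-edge gap <= gap;
    returns clusters of input indices (brute-force O(n^2) union-find)."""
    n = len(points)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = points[i], points[j]
            d = max(s1, s2) - min(e1, e2)
            if d <= gap:
                parent[find(i)] = find(j)
    clusters: Dict[int, List[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return sorted(clusters.values())
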