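"""Interval arithmetic on 0-based half-open genomic intervals.

All coordinates inside the package use a single convention: 0-based,
half-open ``[start, end)``. Dialect-specific conventions (RepeatMasker
1-based inclusive, VCF 1-based) are converted at the I/O boundary.

The functions here operate on plain ``(start, end)`` tuples grouped per
chromosome; higher-level modules wrap them with chromosome bookkeeping.
They are deliberately simple (sort + sweep) so that they can be checked
against per-base brute force on small inputs.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]

STRANDS = ("+", "-", "unknown")


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic span on a named sequence, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(ivs: Iterable[Interval], gap: int = 0) -> List[Interval]:
    """Merge intervals whose gap to the previous merged block is <= ``gap``."""
    out: List[Interval] = []
    for s, e in sorted(ivs):
        if out and s - out[-1][1] <= gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Parts of ``a`` not covered by ``b``."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


def covered_length(query: Interval, ivs: Sequence[Interval]) -> int:
    """Base pairs of ``query`` covered by the union of ``ivs``."""
    s, e = query
    return total_length(intersect_intervals([(s, e)], list(ivs)))


def overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def edge_distance(a: Interval, b: Interval) -> int:
    """Distance between closest edges; 0 when the intervals overlap or abut."""
    if a[0] >= b[1]:
        return a[0] - b[1]
    if b[0] >= a[1]:
        return b[0] - a[1]
    return 0


class IntervalIndex:
    """Sorted-array index for near-neighbour queries on merged intervals.

    Mirrors ``bedtools window -w`` semantics: a query is "within w" of the
    set when its closest-edge distance to some interval is <= w.
    """

    def __init__(self, ivs: Iterable[Interval]):
        self._ivs = merge_intervals(ivs)
        self._starts = [s for s, _ in self._ivs]
        self._ends = [e for _, e in self._ivs]

    def __len__(self) -> int:
        return len(self._ivs)

    def within(self, query: Interval, w: int) -> bool:
        if not self._ivs:
            return False
        s, e = query[0] - w, query[1] + w
        i = bisect_right(self._starts, e) - 1
        # candidate intervals around the padded query
        for k in (i, i + 1):
            if 0 <= k < len(self._ivs):
                if self._ivs[k][0] < e and self._ivs[k][1] > s:
                    return True
                if edge_distance((query[0], query[1]), self._ivs[k]) <= w:
                    return True
        return False

    def overlapping(self, query: Interval) -> List[Interval]:
        out = []
        i = bisect_left(self._ends, query[0] + 1) if self._ends else 0
        while i < len(self._ivs) and self._ivs[i][0] < query[1]:
            if overlap_len(self._ivs[i], query) > 0 or (
                self._ivs[i][0] < query[1] and self._ivs[i][1] > query[0]
            ):
                out.append(self._ivs[i])
            i += 1
        return out


@dataclass
class ExclusionSet:
    """Per-genome exclusion intervals (duplications, gaps, tandem repeats)."""

    intervals: Dict[str, Dict[str, List[Interval]]] = field(default_factory=dict)

    def add(self, genome: str, chrom: str, start: int, end: int) -> None:
        self.intervals.setdefault(genome, {}).setdefault(chrom, []).append((start, end))

    def index(self, genome: str, chrom: str) -> IntervalIndex:
        return IntervalIndex(self.intervals.get(genome, {}).get(chrom, []))

    def per_chrom(self, genome: str) -> Dict[str, List[Interval]]:
        return {c: merge_intervals(v) for c, v in self.intervals.get(genome, {}).items()}

    def total_length(self, genome: str) -> int:
        return sum(total_length(v) for v in self.intervals.get(genome, {}).values())
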