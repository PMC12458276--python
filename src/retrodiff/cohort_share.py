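"""Multi-sample aggregation: callable regions, locus merging, sharing.

Pairwise loci (each sample compared against the common outgroup) are
anchored on outgroup coordinates, restricted to regions callable in every
comparison, merged across samples at a 100 bp gap, and converted into a
presence/absence matrix over all samples plus a synthetic all-absent
"ancestor" row representing the empty ancestral state at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .intervals import intersect_intervals, merge_intervals, subtract_intervals
from .io_formats import DimorphicLocus

MERGE_GAP = 100
ANCESTOR = "ancestor"


def round_percent(k: int, n: int) -> float:
    """Percentage at 0.1 precision, half-up (the printed convention)."""
    if n == 0:
        return 0.0
    return float(
        Decimal(str(100.0 * k / n)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def compute_callable(
    per_pair_coverage: Dict[str, Dict[str, Sequence[Tuple[int, int]]]],
    outgroup_exclusions: Dict[str, Sequence[Tuple[int, int]]],
    chroms: Optional[Iterable[str]] = None,
) -> Dict[str, List[Tuple[int, int]]]:
    """Outgroup regions covered by one query contig in *every* comparison,
    minus outgroup duplications/gaps."""
    pairs = list(per_pair_coverage)
    if chroms is None:
        chroms = sorted({c for cov in per_pair_coverage.values() for c in cov})
    out: Dict[str, List[Tuple[int, int]]] = {}
    for chrom in chroms:
        cur: Optional[List[Tuple[int, int]]] = None
        for pair in pairs:
            ivs = merge_intervals(list(per_pair_coverage[pair].get(chrom, [])))
            cur = ivs if cur is None else intersect_intervals(cur, ivs)
        if cur is None:
            cur = []
        out[chrom] = subtract_intervals(cur, list(outgroup_exclusions.get(chrom, [])))
    return out


def filter_to_callable(
    loci: Sequence[DimorphicLocus],
    callable_regions: Dict[str, List[Tuple[int, int]]],
    chrom_lengths: Dict[str, int],
) -> List[DimorphicLocus]:
    """Drop loci whose outgroup interval touches any non-callable base."""
    non_callable = {
        chrom: subtract_intervals([(0, L)], callable_regions.get(chrom, []))
        for chrom, L in chrom_lengths.items()
    }
    out = []
    for loc in loci:
        bad = non_callable.get(loc.target_chrom, [])
        s, e = loc.target_start, max(loc.target_end, loc.target_start + 1)
        if any(bs < e and be > s for bs, be in bad):
            continue
        out.append(loc)
    return out


@dataclass
class MergedLocus:
    locus_id: str
    chrom: str
    start: int
    end: int
    kind: str
    element_class: str
    present: Set[str]  # samples carrying the element (outgroup included)
    members: List[DimorphicLocus] = field(default_factory=list)

    @property
    def stringent_tsd(self) -> bool:
        return any(m.tsd_len >= 10 for m in self.members)


@dataclass
class PresenceMatrix:
    loci: List[MergedLocus]
    samples: List[str]  # all assemblies, then the synthetic ancestor last
    values: np.ndarray  # loci x samples, bool

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.loci), len(self.samples)):
            raise ValueError("matrix shape mismatch")
        anc = self.samples.index(ANCESTOR)
        if self.values[:, anc].any():
            raise ValueError("ancestor row must be all-absent")
        if len(self.loci) and not self.values[:, [i for i in range(len(self.samples)) if i != anc]].any(axis=1).all():
            raise ValueError("every locus must be present in >= 1 sample")

    @property
    def assembly_samples(self) -> List[str]:
        return [s for s in self.samples if s != ANCESTOR]


def merge_loci(
    loci: Sequence[DimorphicLocus],
    samples: Sequence[str],
    outgroup: str,
    gap: int = MERGE_GAP,
) -> Tuple[List[MergedLocus], int]:
    """Single-linkage clustering of pairwise loci at <= ``gap`` bp in
    outgroup coordinates.

    A cluster is a single underlying variant when all members agree in kind
    and element class and no sample contributes two calls; clusters holding
    more than one distinct variant are discarded. Presence vectors:
    insertion-type loci are present in exactly the calling samples;
    deletion-type loci (element fixed in the outgroup side) are present in
    the outgroup and every sample *without* a deletion call.
    """
    discarded = 0
    merged: List[MergedLocus] = []
    by_chrom: Dict[str, List[DimorphicLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.target_chrom, []).append(loc)
    counter = 0
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: (l.target_start, l.target_end))
        cluster: List[DimorphicLocus] = []
        cluster_end = None
        for loc in group + [None]:
            if loc is not None and cluster and loc.target_start - cluster_end <= gap:
                cluster.append(loc)
                cluster_end = max(cluster_end, loc.target_end)
                continue
            if cluster:
                counter += 1
                m = _resolve_cluster(cluster, samples, outgroup, f"locus{counter:05d}")
                if m is None:
                    discarded += 1
                else:
                    merged.append(m)
            if loc is not None:
                cluster = [loc]
                cluster_end = loc.target_end
        # (trailing None flushes the last cluster)
    return merged, discarded


def _resolve_cluster(cluster, samples, outgroup, locus_id) -> Optional[MergedLocus]:
    kinds = {l.kind for l in cluster}
    classes = {l.element_class for l in cluster}
    callers = [l.sample_id for l in cluster]
    if len(kinds) > 1 or len(classes) > 1 or len(callers) != len(set(callers)):
        return None
    kind = kinds.pop()
    if kind == "insertion":
        present = set(callers)
    else:
        present = (set(samples) - set(callers)) | {outgroup}
    return MergedLocus(
        locus_id=locus_id,
        chrom=cluster[0].target_chrom,
        start=min(l.target_start for l in cluster),
        end=max(l.target_end for l in cluster),
        kind=kind,
        element_class=classes.pop(),
        present=present,
        members=list(cluster),
    )


def presence_matrix(merged: Sequence[MergedLocus], samples: Sequence[str]) -> PresenceMatrix:
    cols = list(samples) + [ANCESTOR]
    values = np.zeros((len(merged), len(cols)), dtype=bool)
    for i, m in enumerate(merged):
        for s in m.present:
            values[i, cols.index(s)] = True
    return PresenceMatrix(list(merged), cols, values)


def sharing_profile(matrix: PresenceMatrix):
    """UpSet-style exact pattern counts plus the singleton summary."""
    samples = matrix.assembly_samples
    idx = [matrix.samples.index(s) for s in samples]
    patterns: Dict[Tuple[str, ...], int] = {}
    singletons = 0
    for row in matrix.values:
        present = tuple(s for s, i in zip(samples, idx) if row[i])
        patterns[present] = patterns.get(present, 0) + 1
        if len(present) == 1:
            singletons += 1
    total = len(matrix.loci)
    return {
        "patterns": patterns,
        "total": total,
        "singletons": singletons,
        "singleton_percent": round_percent(singletons, total),
    }


def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\telement_class\t" + "\t".join(matrix.samples) + "\n")
        for m, row in zip(matrix.loci, matrix.values):
            cells = "\t".join("1" if v else "0" for v in row)
            fh.write(f"{m.locus_id}\t{m.chrom}\t{m.start}\t{m.end}\t{m.element_class}\t{cells}\n")
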