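"""LINE-1 3' transduction detection and source tracing.

RNA polymerase II read-through past the weak LINE-1 terminator carries
downstream genomic sequence into new insertions; that transduced tail
fingerprints the parent element. For each dimorphic LINE-1 the sequence
between the element annotation's 3' end and the variant boundary is
extracted, low-complexity content is masked (sdust-style), and the
remaining candidates are searched against the outgroup genome with a
deterministic seed-and-extend aligner (11-mer exact seeds, edit-distance
extension). Hits are filtered the way the field filters blat output:
>= 95 % identity, >= 25 matched bases, >= 25 unmasked query bases, a
span within 100 bp of the query length, more than 10 kb away from the
locus itself, at most 50 hits per candidate and 5 per locus. Hit
positions adjacent to (and downstream of, in the right orientation) an
annotated LINE-1 identify the parent; merged hit clusters backing more
than one independent insertion flag recurrent "hot" sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import edlib

from ._seq import revcomp
from .breakpoint_refine import RefinedLocus
from .intervals import GenomeInterval, merge_intervals
from .io_formats import RepeatAnnotation

MIN_CANDIDATE = 25
MIN_UNMASKED = 25
MIN_MATCH = 25
MIN_IDENTITY = 0.95
SELF_EXCLUSION = 10_000
SPAN_SLOP = 100
MAX_HITS = 50
MAX_PER_LOCUS = 5
ADJACENCY_WINDOW = 50
SOURCE_MERGE_GAP = 100
SEED_K = 11
SEED_STRIDE = 5


@dataclass
class TransductionCandidate:
    locus_id: str
    chrom: str  # outgroup chromosome of the dimorphic locus
    locus_pos: int  # outgroup coordinate of the locus (self-exclusion anchor)
    seq: str  # element-orientation sequence, 3' of the LINE-1 annotation
    unmasked_bp: int = -1  # filled in by mask_low_complexity
    masked: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class TransductionHit:
    locus_id: str
    target: GenomeInterval
    identity: float
    match_bp: int
    strand: str
    parent_adjacent: bool = False
    source_cluster_id: int = -1


def extract_candidate(
    refined: RefinedLocus,
    annotations: Sequence[RepeatAnnotation],
    locus_id: str,
    outgroup_pos: int,
    min_len: int = MIN_CANDIDATE,
) -> Optional[TransductionCandidate]:
    """Candidate 3' transduction of one refined LINE-1 locus.

    The longest LINE-1 annotation intersecting the insert defines the
    element's 3' end; the candidate runs from there to the 3' boundary of
    the between-TSD region, read in element orientation. Candidates
    shorter than 25 bp yield ``None``.
    """
    iv = refined.filled_interval
    best = None
    for a in annotations:
        if a.interval.chrom != iv.chrom:
            continue
        ov = min(a.interval.end, iv.end) - max(a.interval.start, iv.start)
        if ov <= 0 or not a.repeat_class.upper().startswith("LINE"):
            continue
        if best is None or len(a.interval) > len(best.interval):
            best = a
    if best is None:
        return None
    region_start = iv.start + refined.tsd_len  # between-TSD region
    region_end = iv.end
    fseq_region = refined.between_tsd_seq
    if best.interval.strand == "-":
        # element 3' end is at the annotation's genomic start
        end = max(region_start, min(best.interval.start, region_end))
        tail = fseq_region[: end - region_start]
        seq = revcomp(tail)
    else:
        start = max(region_start, min(best.interval.end, region_end))
        seq = fseq_region[start - region_start :]
    if len(seq) < min_len:
        return None
    return TransductionCandidate(
        locus_id=locus_id, chrom=iv.chrom, locus_pos=outgroup_pos, seq=seq
    )


# ---------------------------------------------------------------------------
# masking


def dust_mask(seq: str, window: int = 64, threshold: float = 20.0) -> List[Tuple[int, int]]:
    """Symmetric DUST-style low-complexity mask.

    Each window is scored as 10 * sum(c_t * (c_t - 1) / 2) / (w - 3) over
    its triplet counts; inside a window above the threshold, the positions
    of the repeated triplets (count >= 3) are masked — the run itself,
    not its unique neighbourhood.
    """
    n = len(seq)
    masked: List[Tuple[int, int]] = []
    if n < 4:
        return masked
    step = max(1, window // 2)
    for s in range(0, max(1, n - 2), step):
        w = seq[s : s + window]
        if len(w) < 4:
            continue
        counts: Dict[str, int] = {}
        positions: Dict[str, List[int]] = {}
        for i in range(len(w) - 2):
            t = w[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
            positions.setdefault(t, []).append(i)
        score = 10.0 * sum(c * (c - 1) / 2 for c in counts.values()) / (len(w) - 3)
        if score > threshold:
            for t, c in counts.items():
                if c >= 3:
                    for i in positions[t]:
                        masked.append((s + i, min(n, s + i + 3)))
    return merge_intervals(masked)


def mask_low_complexity(
    candidate: TransductionCandidate,
    element_library: Sequence[str] = (),
    min_unmasked: int = MIN_UNMASKED,
) -> Optional[TransductionCandidate]:
    """Mask low-complexity runs (and exact element-library k-mers); discard
    candidates with fewer than 25 unmasked bases. The original, unmasked
    sequence remains what is searched."""
    masked = dust_mask(candidate.seq)
    for lib in element_library:
        masked.extend(_library_matches(candidate.seq, lib))
    masked = merge_intervals(masked)
    unmasked = len(candidate.seq) - sum(e - s for s, e in masked)
    candidate.masked = masked
    candidate.unmasked_bp = unmasked
    if unmasked < min_unmasked:
        return None
    return candidate


def _library_matches(seq: str, lib: str, k: int = 20) -> List[Tuple[int, int]]:
    out = []
    lib_kmers = {lib[i : i + k] for i in range(0, len(lib) - k + 1)}
    rc = revcomp(lib)
    lib_kmers |= {rc[i : i + k] for i in range(0, len(rc) - k + 1)}
    for i in range(0, len(seq) - k + 1):
        if seq[i : i + k] in lib_kmers:
            out.append((i, i + k))
    return merge_intervals(out)


# ---------------------------------------------------------------------------
# genome search


def _trim_polya(seq: str) -> Tuple[str, int]:
    """Strip terminal homopolymer A/T runs (the post-transcriptional tails);
    returns (core, left_offset)."""
    n = len(seq)
    i = 0
    while i < n and seq[i] in "AT" and _run_len(seq, i) >= 5:
        i += _run_len(seq, i)
    j = n
    while j > i and seq[j - 1] in "AT" and _run_len_back(seq, j) >= 5:
        j -= _run_len_back(seq, j)
    return seq[i:j], i


def _run_len(seq: str, i: int) -> int:
    b = seq[i]
    j = i
    while j < len(seq) and seq[j] == b:
        j += 1
    return j - i


def _run_len_back(seq: str, j: int) -> int:
    b = seq[j - 1]
    i = j
    while i > 0 and seq[i - 1] == b:
        i -= 1
    return j - i


def search_genome(
    candidate: TransductionCandidate,
    outgroup: Dict[str, str],
    allowed_chroms: Optional[Set[str]] = None,
    min_identity: float = MIN_IDENTITY,
    min_match: int = MIN_MATCH,
    self_exclusion: int = SELF_EXCLUSION,
    span_slop: int = SPAN_SLOP,
    max_hits: int = MAX_HITS,
) -> List[TransductionHit]:
    """Seed-and-extend search of one candidate against the outgroup genome.

    Returns the filtered hit list; an empty list when the candidate is
    voided (no qualifying hit, or more than ``max_hits`` raw placements,
    the repetitive-sequence guard).
    """
    core, _off = _trim_polya(candidate.seq)
    if len(core) < min_match:
        return []
    if candidate.masked:  # unmasked bases inside the searched core
        masked_in_core = sum(
            max(0, min(e, _off + len(core)) - max(s, _off)) for s, e in candidate.masked
        )
        if len(core) - masked_in_core < MIN_UNMASKED:
            return []
    windows = _seed_windows(core, outgroup, allowed_chroms)
    if len(windows) > max_hits:
        return []
    hits: List[TransductionHit] = []
    for chrom, wstart, wend, strand in windows:
        segment = outgroup[chrom][wstart:wend]
        query = core if strand == "+" else revcomp(core)
        aln = edlib.align(query, segment, mode="HW", task="locations")
        if aln["editDistance"] < 0:
            continue
        identity = 1.0 - aln["editDistance"] / len(query)
        match_bp = len(query) - aln["editDistance"]
        if identity < min_identity or match_bp < min_match:
            continue
        loc = aln["locations"][0]
        tstart, tend = wstart + loc[0], wstart + loc[1] + 1
        if allowed_chroms is not None and chrom not in allowed_chroms:
            continue
        if chrom == candidate.chrom and _edge_dist(tstart, tend, candidate.locus_pos) <= self_exclusion:
            continue
        if abs((tend - tstart) - len(core)) > span_slop:
            continue
        hits.append(
            TransductionHit(
                locus_id=candidate.locus_id,
                target=GenomeInterval(chrom, tstart, tend, strand),
                identity=identity,
                match_bp=match_bp,
                strand=strand,
            )
        )
    # deduplicate overlapping placements from adjacent seed windows
    hits = _dedup_hits(hits)
    return hits


def _edge_dist(s: int, e: int, pos: int) -> int:
    if pos < s:
        return s - pos
    if pos > e:
        return pos - e
    return 0


def _seed_windows(core: str, outgroup: Dict[str, str], allowed_chroms):
    """Exact k-mer seed placements expanded to candidate windows.

    Anchors (implied core start positions) are clustered per chromosome
    and strand; a window qualifies when at least two distinct seeds place
    the core consistently (one suffices only for cores too short to carry
    two seeds). This is the tiled-seed requirement that keeps random
    11-mer matches from flooding the hit list.
    """
    margin = len(core) + 50
    seeds = [
        (off, core[off : off + SEED_K])
        for off in range(0, max(1, len(core) - SEED_K + 1), SEED_STRIDE)
    ]
    min_support = 2 if len(seeds) >= 2 else 1
    windows = []
    for chrom, seq in outgroup.items():
        if allowed_chroms is not None and chrom not in allowed_chroms:
            continue
        for strand in ("+", "-"):
            anchors: Dict[int, Set[int]] = {}
            for off, kmer in seeds:
                probe = kmer if strand == "+" else revcomp(kmer)
                i = seq.find(probe)
                while i != -1:
                    anchor = i - off if strand == "+" else i - (len(core) - off - SEED_K)
                    anchors.setdefault(anchor // 32, set()).add(off)
                    i = seq.find(probe, i + 1)
            for bucket in sorted(anchors):
                support = set(anchors[bucket])
                for nb in (bucket - 1, bucket + 1):
                    support |= anchors.get(nb, set())
                if len(support) < min_support:
                    continue
                wstart = max(0, bucket * 32 - 50)
                windows.append((chrom, wstart, min(len(seq), wstart + margin + 100), strand))
    return _merge_windows(sorted(set(windows)))


def _merge_windows(windows):
    out = []
    for chrom, s, e, strand in windows:
        if out and out[-1][0] == chrom and out[-1][3] == strand and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e), strand)
        else:
            out.append((chrom, s, e, strand))
    return out


def _dedup_hits(hits: List[TransductionHit]) -> List[TransductionHit]:
    hits = sorted(hits, key=lambda h: (h.target.chrom, h.target.start, -h.match_bp))
    out: List[TransductionHit] = []
    for h in hits:
        if out:
            p = out[-1]
            if (
                p.target.chrom == h.target.chrom
                and h.target.start < p.target.end
                and p.target.start < h.target.end
            ):
                continue
        out.append(h)
    return out


# ---------------------------------------------------------------------------
# source classification


def classify_sources(
    hits_by_locus: Dict[str, List[TransductionHit]],
    outgroup_line1s: Sequence[RepeatAnnotation],
    max_per_locus: int = MAX_PER_LOCUS,
    adjacency_window: int = ADJACENCY_WINDOW,
    merge_gap: int = SOURCE_MERGE_GAP,
    locus_positions: Optional[Dict[str, Tuple[str, int]]] = None,
) -> dict:
    """Parent adjacency and recurrent-source clustering over all samples.

    A hit is parent-adjacent when a LINE-1 annotation lies within 50 bp,
    its 3' end sits upstream of the hit in concordant orientation (the
    transduced sequence is downstream of the element), and the annotation
    is neither wholly inside the hit nor wholly containing it. Hits merged
    at <= 100 bp gaps form source clusters; clusters backing more than one
    independent insertion are flagged recurrent.
    """
    kept: List[TransductionHit] = []
    for locus_id, hits in hits_by_locus.items():
        if 0 < len(hits) <= max_per_locus:
            kept.extend(hits)
    line1_by_chrom: Dict[str, List[RepeatAnnotation]] = {}
    for a in outgroup_line1s:
        if a.repeat_class.upper().startswith("LINE") and "HAL" not in a.repeat_class.upper():
            line1_by_chrom.setdefault(a.interval.chrom, []).append(a)
    for h in kept:
        h.parent_adjacent = _is_parent_adjacent(
            h, line1_by_chrom.get(h.target.chrom, []), adjacency_window
        )
    clusters = _cluster_hits(kept, merge_gap)
    recurrent = []
    for cid, members in clusters.items():
        loci = {m.locus_id for m in members}
        if _independent_insertions(loci, locus_positions, merge_gap) > 1:
            recurrent.append(
                dict(
                    cluster_id=cid,
                    chrom=members[0].target.chrom,
                    start=min(m.target.start for m in members),
                    end=max(m.target.end for m in members),
                    loci=sorted(loci),
                )
            )
    return {
        "hits": kept,
        "n_clusters": len(clusters),
        "recurrent_sources": recurrent,
    }


def _independent_insertions(
    loci: Set[str],
    locus_positions: Optional[Dict[str, Tuple[str, int]]],
    gap: int,
) -> int:
    """Distinct underlying insertions among the loci of one source cluster.

    The same shared variant observed in several pairwise comparisons maps
    to nearly identical outgroup coordinates; collapse loci within the
    merge gap before declaring a source recurrent."""
    if locus_positions is None:
        return len(loci)
    coords = sorted(
        locus_positions.get(l, (f"?{l}", 0)) for l in loci
    )
    groups = 0
    prev = None
    for chrom, pos in coords:
        if prev is None or chrom != prev[0] or pos - prev[1] > gap:
            groups += 1
        prev = (chrom, max(pos, prev[1]) if prev and chrom == prev[0] else pos)
    return groups


def _is_parent_adjacent(hit: TransductionHit, line1s, window: int) -> bool:
    hs, he = hit.target.start, hit.target.end
    for a in line1s:
        s, e = a.interval.start, a.interval.end
        if s >= hs and e <= he:
            continue  # annotation wholly inside the transduced segment
        if s <= hs and e >= he:
            continue  # annotation swallows the whole hit
        if max(hs, s) - min(he, e) > window and _gap(hs, he, s, e) > window:
            continue
        if _gap(hs, he, s, e) > window:
            continue
        strand = a.interval.strand
        if strand == "+":
            # 3' end at e; the transduction must lie downstream (right)
            if hit.strand == "+" and hs >= e - window:
                return True
        elif strand == "-":
            if hit.strand == "-" and he <= s + window:
                return True
    return False


def _gap(hs, he, s, e) -> int:
    if s >= he:
        return s - he
    if hs >= e:
        return hs - e
    return 0


def _cluster_hits(hits: List[TransductionHit], gap: int) -> Dict[int, List[TransductionHit]]:
    clusters: Dict[int, List[TransductionHit]] = {}
    cid = -1
    prev_chrom, prev_end = None, None
    for h in sorted(hits, key=lambda h: (h.target.chrom, h.target.start)):
        if prev_chrom == h.target.chrom and h.target.start - prev_end <= gap:
            clusters[cid].append(h)
            prev_end = max(prev_end, h.target.end)
        else:
            cid += 1
            clusters[cid] = [h]
            prev_chrom, prev_end = h.target.chrom, h.target.end
        h.source_cluster_id = cid
    return clusters
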