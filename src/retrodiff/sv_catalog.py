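"""Filtering raw SV calls into candidate dimorphic LINE-1/SINEC loci.

The filters reproduce the discovery cascade used for assembly-vs-assembly
mobile-element calling: a 50 bp size floor, an allowed-chromosome list,
same-chromosome query/target placement, a 100 bp proximity exclusion
around unreliable regions (``bedtools window -w 100 -v`` semantics:
closest-edge distance <= 100 removes the call), and a 70 %
repeat-content rule that classifies each surviving SV as LINE-1, SINEC or
other using the annotations of whichever genome carries the element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .intervals import (
    ExclusionSet,
    GenomeInterval,
    covered_length,
    merge_intervals,
    subtract_intervals,
    total_length,
)
from .io_formats import RepeatAnnotation, SnvRecord, StructuralVariantCall

MIN_SV_LEN = 50
EXCLUSION_WINDOW = 100
REPEAT_FRACTION = 0.7

DEFAULT_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 39))


@dataclass
class CandidateLocus:
    call: StructuralVariantCall
    element_class: str  # LINE1 | SINEC | other
    repeat_fraction: float
    filled_genome: str  # id of the genome carrying the element

    def __post_init__(self) -> None:
        if self.element_class not in ("LINE1", "SINEC", "other"):
            raise ValueError(f"bad element_class {self.element_class!r}")
        if self.element_class != "other" and self.repeat_fraction < REPEAT_FRACTION:
            raise ValueError("classified locus below the repeat-content threshold")


def filter_svs(
    calls: Sequence[StructuralVariantCall],
    exclusions: ExclusionSet,
    allowed_chroms: Iterable[str],
    target_genome: str,
    query_genome: str,
    min_len: int = MIN_SV_LEN,
    window: int = EXCLUSION_WINDOW,
) -> List[StructuralVariantCall]:
    """Size, chromosome and exclusion-proximity filtering (pure; idempotent)."""
    allowed = set(allowed_chroms)
    out: List[StructuralVariantCall] = []
    t_idx: Dict[str, object] = {}
    q_idx: Dict[str, object] = {}
    for call in calls:
        if call.length < min_len:
            continue
        if call.target.chrom not in allowed:
            continue
        if call.target.chrom != call.query.chrom:
            continue
        chrom = call.target.chrom
        if chrom not in t_idx:
            t_idx[chrom] = exclusions.index(target_genome, chrom)
            q_idx[chrom] = exclusions.index(query_genome, chrom)
        if t_idx[chrom].within((call.target.start, call.target.end), window):
            continue
        if q_idx[chrom].within((call.query.start, call.query.end), window):
            continue
        out.append(call)
    return out


def classify_repeat_content(
    sv: StructuralVariantCall,
    annotations: Sequence[RepeatAnnotation],
    filled_genome: str,
    threshold: float = REPEAT_FRACTION,
) -> CandidateLocus:
    """Assign LINE1/SINEC when >= 70 % of the filled-site interval is covered
    by same-class annotations; HAL-family LINEs never count toward LINE-1.

    ``annotations`` must come from the genome carrying the inserted
    sequence; the relevant interval is that genome's side of the call.
    """
    iv = sv.query if sv.filled_side == "query" else sv.target
    if len(iv) == 0:
        raise ValueError("zero-length filled-site interval")
    per_class: Dict[str, List[Tuple[int, int]]] = {}
    for a in annotations:
        if a.interval.chrom != iv.chrom:
            continue
        if a.interval.end <= iv.start or a.interval.start >= iv.end:
            continue
        cls = _element_class(a)
        if cls is None:
            continue
        per_class.setdefault(cls, []).append((a.interval.start, a.interval.end))
    best_cls, best_frac = "other", 0.0
    for cls, ivs in per_class.items():
        frac = covered_length((iv.start, iv.end), merge_intervals(ivs)) / len(iv)
        if frac > best_frac:
            best_cls, best_frac = cls, frac
    if best_frac < threshold:
        best_cls = "other"
    filled = filled_genome
    return CandidateLocus(sv, best_cls, best_frac, filled)


def _element_class(a: RepeatAnnotation) -> Optional[str]:
    rc = a.repeat_class.upper()
    if "HAL" in rc or a.subfamily.upper().startswith("HAL"):
        return None  # HAL-family LINEs are excluded from LINE-1 entirely
    if rc.startswith("LINE"):
        return "LINE1" if "L1" in rc or a.subfamily.upper().startswith("L1") else None
    if rc.startswith("SINE"):
        return "SINEC"
    return None


def extract_snvs(
    snvs: Sequence[SnvRecord],
    aligned_regions: Dict[str, Sequence[Tuple[int, int]]],
    low_complexity: Dict[str, Sequence[Tuple[int, int]]],
    allowed_chroms: Optional[Iterable[str]] = None,
) -> Tuple[int, int]:
    """Count usable SNVs and the aligned length they were called in.

    Low-complexity/low-confidence regions of the *target* genome are
    subtracted from the aligned regions; SNVs falling outside the remaining
    intervals are not counted. Returns ``(snv_count, aligned_bp)``.
    """
    allowed: Optional[Set[str]] = set(allowed_chroms) if allowed_chroms is not None else None
    count = 0
    aligned_bp = 0
    kept: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, regions in aligned_regions.items():
        if allowed is not None and chrom not in allowed:
            continue
        remain = subtract_intervals(list(regions), list(low_complexity.get(chrom, [])))
        kept[chrom] = remain
        aligned_bp += total_length(remain)
    for s in snvs:
        ivs = kept.get(s.chrom)
        if not ivs:
            continue
        if any(a <= s.pos < b for a, b in ivs):
            count += 1
    return count, aligned_bp
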