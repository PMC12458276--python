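"""Hallmarks of target-primed reverse transcription at refined loci.

A LINE-1-mediated insertion leaves a characteristic anatomy: a target
site duplication (TSD) flanking the insert, a 3' poly(A) tail abutting
the downstream TSD copy, and an endonuclease nick site matching the
ORF2p consensus (5'-TTTTT/AA read on the minus strand). This module
detects each hallmark on a refined locus, assigns element orientation
and subfamily from overlapping repeat annotations, and classifies loci
under the stringent thresholds (TSD >= 10 bp, poly(A) >= 10 bp within
5 bp of the TSD) and a relaxed reanalysis mode (TSD >= 7 bp; degraded
poly(A) evidence = a 15 bp window with >= 10 As within 30 bp of the TSD).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import find_polya, relaxed_polya_evidence, revcomp
from .breakpoint_refine import RefinedLocus
from .io_formats import RepeatAnnotation

MIN_SEGMENT = 20  # annotation segments below this never vote
TSD_HIGH_CONF = 10
POLYA_MIN = 10
POLYA_MAX_GAP = 5
RELAXED_TSD_MIN = 7

CLASSES = ("both", "tsd_only", "polya_only", "neither", "ambiguous")
MERGED_SINEC_LABEL = "SINEC_Cf/2A1"
_SINEC_MERGE = {"SINEC_CF", "SINEC2A1_CF"}


@dataclass
class HallmarkProfile:
    orientation: str  # + | - | ambiguous
    tsd_len: int
    polya_len: int
    polya_gap: int
    en_site: str  # 7-mer on the minus strand, or ""
    stringent_class: str
    relaxed_class: str
    subfamily: str


def _segments(
    refined: RefinedLocus,
    annotations: Sequence[RepeatAnnotation],
    interval: Tuple[int, int],
    min_segment: int = MIN_SEGMENT,
) -> List[Tuple[RepeatAnnotation, int]]:
    """Class-matching annotation segments overlapping ``interval`` by >= 20 bp."""
    want = refined.candidate.element_class
    chrom = refined.filled_interval.chrom
    out = []
    for a in annotations:
        if a.interval.chrom != chrom:
            continue
        ov = min(a.interval.end, interval[1]) - max(a.interval.start, interval[0])
        if ov < min_segment:
            continue
        rc = a.repeat_class.upper()
        is_line1 = rc.startswith("LINE") and "HAL" not in rc
        is_sinec = rc.startswith("SINE")
        if (want == "LINE1" and is_line1) or (want == "SINEC" and is_sinec):
            out.append((a, ov))
    return out


def detect_orientation(
    refined: RefinedLocus, annotations: Sequence[RepeatAnnotation]
) -> Optional[str]:
    """Orientation vote by >= 20 bp annotation segments over the insert.

    Unanimous segments give the strand; conflicting strands give
    ``"ambiguous"`` (locus kept, poly(A) skipped); no qualifying segment
    returns ``None`` and the locus is removed from hallmark analysis.
    """
    iv = refined.filled_interval
    segs = _segments(refined, annotations, (iv.start, iv.end))
    if not segs:
        return None
    strands = {a.interval.strand for a, _ in segs}
    if strands == {"+"}:
        return "+"
    if strands == {"-"}:
        return "-"
    return "ambiguous"


def detect_polya(
    refined: RefinedLocus,
    orientation: str,
    min_len: int = POLYA_MIN,
    max_gap: int = POLYA_MAX_GAP,
) -> Tuple[int, int]:
    """Longest homopolymer tail in the between-TSD region within ``max_gap``
    of the element's 3' boundary; reported only at ``min_len`` or longer.
    Returns ``(length, gap)`` or ``(0, -1)``."""
    if orientation not in ("+", "-"):
        return (0, -1)
    ln, gap = find_polya(refined.between_tsd_seq, orientation, max_gap=max_gap, min_len=min_len)
    return (ln, gap)


def extract_en_site(
    refined: RefinedLocus, orientation: str, min_tsd: int = TSD_HIGH_CONF
) -> str:
    """The 7-mer endonuclease cleavage site, reported on the minus strand.

    Requires a high-confidence TSD and a defined orientation. For a
    plus-orientation element the site is the reverse complement of the two
    bases 5' of the upstream TSD copy plus the first five TSD bases; the
    minus-orientation case mirrors this at the downstream TSD copy so that
    canonical sites from both orientations superimpose as TTTTT/AA.
    """
    t = refined.tsd_len
    if t < min_tsd or orientation not in ("+", "-"):
        return ""
    if orientation == "+":
        up2 = refined.filled_left_context[-2:]
        first5 = refined.tsd_seq[:5]
        if len(up2) < 2:
            return ""
        return revcomp(up2 + first5)
    right = refined.filled_right_context
    if len(right) < t + 2:
        return ""
    last5 = right[t - 5 : t]
    down2 = right[t : t + 2]
    return last5 + down2


def classify_hallmarks(
    orientation: str,
    tsd_len: int,
    polya_len: int,
    polya_gap: int,
    between_tsd_seq: str,
    mode: str = "stringent",
    tsd_min: int = TSD_HIGH_CONF,
    relaxed_tsd_min: int = RELAXED_TSD_MIN,
    polya_min: int = POLYA_MIN,
    polya_max_gap: int = POLYA_MAX_GAP,
) -> str:
    if orientation not in ("+", "-"):
        return "ambiguous"
    if mode == "stringent":
        has_tsd = tsd_len >= tsd_min
        has_polya = polya_len >= polya_min and 0 <= polya_gap <= polya_max_gap
    elif mode == "relaxed":
        has_tsd = tsd_len >= relaxed_tsd_min
        has_polya = relaxed_polya_evidence(between_tsd_seq, orientation)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if has_tsd and has_polya:
        return "both"
    if has_tsd:
        return "tsd_only"
    if has_polya:
        return "polya_only"
    return "neither"


def assign_subfamily(
    refined: RefinedLocus,
    annotations: Sequence[RepeatAnnotation],
    min_segment: int = MIN_SEGMENT,
) -> str:
    """Subfamily of the element between the TSDs.

    Annotation segments < 20 bp are ignored; multiple distinct subfamilies
    leave the locus ``"unresolved"``; the SINEC_Cf and SINEC2A1_Cf labels
    (identical tRNA heads, differing only in internal repeat length)
    collapse into the merged SINEC_Cf/2A1 subfamily. Returns ``""`` when
    no qualifying segment exists.
    """
    iv = refined.filled_interval
    between = (iv.start + refined.tsd_len, iv.end)
    segs = _segments(refined, annotations, between, min_segment)
    labels = set()
    for a, _ in segs:
        name = a.subfamily
        if name.upper() in _SINEC_MERGE:
            name = MERGED_SINEC_LABEL
        labels.add(name)
    if not labels:
        return ""
    if len(labels) > 1:
        return "unresolved"
    return labels.pop()


def profile_locus(
    refined: RefinedLocus, annotations: Sequence[RepeatAnnotation]
) -> Optional[HallmarkProfile]:
    """Full hallmark annotation of one refined locus; ``None`` when no
    orientation-defining annotation segment exists (locus removed)."""
    orientation = detect_orientation(refined, annotations)
    if orientation is None:
        return None
    polya_len, polya_gap = detect_polya(refined, orientation)
    en = extract_en_site(refined, orientation)
    args = dict(
        orientation=orientation,
        tsd_len=refined.tsd_len,
        polya_len=polya_len,
        polya_gap=polya_gap,
        between_tsd_seq=refined.between_tsd_seq,
    )
    return HallmarkProfile(
        orientation=orientation,
        tsd_len=refined.tsd_len,
        polya_len=polya_len,
        polya_gap=polya_gap,
        en_site=en,
        stringent_class=classify_hallmarks(mode="stringent", **args),
        relaxed_class=classify_hallmarks(mode="relaxed", **args),
        subfamily=assign_subfamily(refined, annotations),
    )


def logo_matrix(en_sites: Sequence[str]) -> pd.DataFrame:
    """Column-wise base counts over 7-mer EN sites (positions 1..7 x ACGT)."""
    counts = np.zeros((7, 4), dtype=int)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for site in en_sites:
        if len(site) != 7:
            raise ValueError(f"EN site {site!r} is not a 7-mer")
        for i, b in enumerate(site):
            if b in order:
                counts[i, order[b]] += 1
    return pd.DataFrame(counts, index=range(1, 8), columns=["A", "C", "G", "T"])
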