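"""Low-level sequence primitives shared by the simulator and the callers.

The insertion-representation conventions live here so that the generative
model and the detection code agree on definitions rather than on
implementation details:

* an insertion is always reported in its *leftmost* representation (the
  breakpoint is slid left while the last inserted base equals the base
  immediately 5' of the breakpoint);
* the target-site duplication is the longest exact common prefix of the
  inserted sequence and the empty-site sequence 3' of the breakpoint
  (three-way identity: both filled-site copies and the empty site match);
* a poly(A) tail is the longest orientation-appropriate homopolymer run
  whose gap to the element's 3' boundary is at most ``max_gap``.
"""

from __future__ import annotations

import re
from typing import List, Optional, Tuple

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def common_prefix_len(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def leftmost_insert(left_context: str, insert: str, right_context: str) -> Tuple[int, str]:
    """Slide an insertion to its leftmost equivalent representation.

    Returns ``(shift, insert')`` where ``shift`` is how many bases the
    breakpoint moved left. ``left_context`` is the empty-site sequence 5' of
    the breakpoint; the representation is equivalent because
    ``left + insert == left[:-k] + insert' + ...`` for rotated inserts.
    """
    shift = 0
    ins = insert
    while shift < len(left_context) and ins and ins[-1] == left_context[-1 - shift]:
        ins = left_context[-1 - shift] + ins[:-1]
        shift += 1
    return shift, ins


def call_tsd_seq(insert: str, empty_right: str, max_mismatch: int = 0) -> str:
    """TSD under the leftmost convention: common prefix of insert and the
    empty site 3' of the breakpoint (which is also the filled-site right
    flank), capped at the insert length.

    ``max_mismatch`` tolerates that many interior substitutions in the
    duplication (a sensitivity-study option; the default demands the
    exact three-way identity). The duplication never ends on a mismatch.
    """
    if max_mismatch <= 0:
        return insert[: common_prefix_len(insert, empty_right)]
    n = min(len(insert), len(empty_right))
    mismatches = 0
    best = 0
    for i in range(n):
        if insert[i] == empty_right[i]:
            best = i + 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
    return insert[:best]


def find_polya(
    region: str, orientation: str, max_gap: int = 5, min_len: int = 1
) -> Tuple[int, int]:
    """Longest eligible homopolymer tail in the between-TSD region.

    Plus-strand elements end in an A-run near the *right* edge of the
    region; minus-strand elements present a T-run near the *left* edge.
    Returns ``(length, gap)`` or ``(0, -1)`` when no run of ``min_len`` or
    longer sits within ``max_gap`` of the 3' boundary. Ties between
    equal-length runs go to the run nearer the boundary.
    """
    if orientation == "+":
        runs = [(m.start(), m.end()) for m in re.finditer(r"A+", region)]
        eligible = [(e - s, len(region) - e) for s, e in runs if len(region) - e <= max_gap]
    elif orientation == "-":
        runs = [(m.start(), m.end()) for m in re.finditer(r"T+", region)]
        eligible = [(e - s, s) for s, e in runs if s <= max_gap]
    else:
        return (0, -1)
    eligible = [(ln, gap) for ln, gap in eligible if ln >= min_len]
    if not eligible:
        return (0, -1)
    # longest wins; among equals the smaller gap (nearer the boundary)
    ln, gap = max(eligible, key=lambda t: (t[0], -t[1]))
    return ln, gap


def find_runs(seq: str, base: str) -> List[Tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(re.escape(base) + "+", seq)]


def relaxed_polya_evidence(
    region: str, orientation: str, window: int = 15, min_a: int = 10, zone: int = 30
) -> bool:
    """Degraded-tail evidence: any ``window``-bp stretch containing at least
    ``min_a`` orientation-appropriate bases within ``zone`` bp of the 3'
    boundary (windows scanned at stride 1)."""
    base = "A" if orientation == "+" else "T"
    n = len(region)
    if n < window:
        seg = region
        return seg.count(base) >= min_a
    if orientation == "+":
        lo = max(0, n - zone - window)
        positions = range(lo, n - window + 1)
    else:
        positions = range(0, min(zone, n - window) + 1)
    for i in positions:
        if region[i : i + window].count(base) >= min_a:
            return True
    return False
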