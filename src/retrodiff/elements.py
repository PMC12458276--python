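"""Synthetic mobile-element consensus library.

Real Repbase consensi are not bundled; instead the simulator implants
fixed synthetic stand-ins: a 200 bp tRNA-derived "SINEC" with a (CT)n
microsatellite core, and a 6 kb "LINE1" whose two long open-reading-frame
regions are junk codons. The sequences are generated once from a fixed
RNG stream so that every run of the package sees identical consensi.

Subfamily label conventions mirror the canine RepeatMasker vocabulary:
recently active SINEC copies are labelled SINEC_Cf or SINEC2A1_Cf (which
downstream analysis collapses into SINEC_Cf/2A1), young LINE-1 copies are
L1_Cf, and ancient fixed copies carry older subfamily names. HAL-family
LINEs exist only as fixed background and never count as LINE-1.
"""

from __future__ import annotations

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _make_library():
    rng = np.random.default_rng(20240117)
    # SINEC: tRNA-Lys-like head, (CT)n core, unique body; ends on a non-A
    head = _random_seq(rng, 72)
    core = "CT" * 14
    body = _random_seq(rng, 200 - len(head) - len(core) - 1)
    sinec = ("G" + head[1:] + core + body).replace("AAAA", "AACA")
    sinec = sinec[:199] + "G"
    # LINE1: 5'UTR + two ORF-like junk-codon regions + 3'UTR, 6000 bp
    line1 = "G" + _random_seq(rng, 5998) + "G"
    line1 = line1.replace("AAAAA", "AACAA")
    # HAL: an extinct LINE half-way relative; 1500 bp
    hal = _random_seq(rng, 1500)
    return sinec, line1, hal


SINEC_CONSENSUS, LINE1_CONSENSUS, HAL_CONSENSUS = _make_library()

SINEC_SUBFAMILIES = ("SINEC_Cf", "SINEC2A1_Cf")
LINE1_YOUNG_SUBFAMILY = "L1_Cf"
LINE1_OLD_SUBFAMILIES = ("L1_Canis1", "L1MEc")
HAL_SUBFAMILY = "HAL1"

SINEC_CLASS = "SINE/tRNA-Lys"
LINE1_CLASS = "LINE/L1"
HAL_CLASS = "LINE/HAL"
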