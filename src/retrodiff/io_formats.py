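"""Readers and writers for on-disk formats.

Supported inputs:

* RepeatMasker ``.out`` tables (1-based inclusive; strand ``C`` for minus),
* BED3/BED6,
* an 8-column ``paftools_tsv`` dialect carrying the fields of
  ``paftools.js call`` variant records the pipeline needs,
* VCF 4.x with full ALT sequences for insertions,
* FASTA (via pyfaidx/plain writer),
* the per-locus TSV table emitted after hallmark calling.

Everything is normalised to the internal convention (0-based half-open,
strand ``+``/``-``/``unknown``) on the way in and converted back on the
way out, so reader/writer pairs round-trip bit-identically on valid files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .intervals import GenomeInterval

MIN_SV_LEN = 50  # variants shorter than this are neither SNV nor SV


class ParseError(ValueError):
    def __init__(self, path, line_no: int, msg: str):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


@dataclass(frozen=True)
class RepeatAnnotation:
    """One annotated repeat interval from a RepeatMasker-style table."""

    interval: GenomeInterval
    repeat_class: str
    subfamily: str
    divergence_pct: float = 0.0

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")


@dataclass(frozen=True)
class SnvRecord:
    chrom: str
    pos: int  # 0-based position on the target genome
    ref: str
    alt: str


@dataclass(frozen=True)
class StructuralVariantCall:
    """A raw insertion/deletion call from one pairwise genome comparison.

    ``kind == "insertion"`` means the query/sample genome carries the extra
    sequence (filled site in the sample); ``"deletion"`` means the target
    genome carries it (filled site in the target).
    """

    target: GenomeInterval
    query: GenomeInterval
    kind: str
    inserted_seq: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad kind {self.kind!r}")
        if len(self.inserted_seq) < 1:
            raise ValueError("SV calls must carry the variant sequence")

    @property
    def length(self) -> int:
        return len(self.inserted_seq)

    @property
    def filled_side(self) -> str:
        return "query" if self.kind == "insertion" else "target"


@dataclass
class DimorphicLocus:
    """A refined candidate insertion with its hallmark annotation."""

    locus_id: str
    sample_id: str
    outgroup_id: str
    kind: str  # insertion (element in sample) | deletion (element in outgroup)
    element_class: str  # LINE1 | SINEC
    target_chrom: str
    target_start: int
    target_end: int
    query_chrom: str
    query_start: int
    query_end: int
    insert_len: int
    tsd_seq: str
    target_site_deletion_len: int
    polya_len: int
    polya_gap: int
    orientation: str
    en_site: str
    stringent_class: str
    relaxed_class: str
    subfamily: str
    flank_used: int
    qc_pass: bool
    qc_reason: str

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)


LOCUS_COLUMNS = [f.name for f in dataclasses.fields(DimorphicLocus)]


# ---------------------------------------------------------------------------
# repeat annotations


def read_repeat_annotation(path, dialect: str) -> List[RepeatAnnotation]:
    """Read repeat annotations; coordinates normalised to 0-based half-open.

    ``rm_out``: RepeatMasker .out (1-based inclusive begin/end, strand C = minus).
    ``bed6``: chrom start end name score strand, already half-open.
    """
    if dialect not in ("rm_out", "bed6"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: List[RepeatAnnotation] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if dialect == "rm_out":
                # skip the two header lines + separator of real .out files
                if fields[0] in ("SW", "score") or line.startswith("---"):
                    continue
                try:
                    div = float(fields[1])
                    chrom = fields[4]
                    start = int(fields[5]) - 1
                    end = int(fields[6])
                    strand = "-" if fields[8] in ("C", "-") else "+"
                    subfamily = fields[9]
                    repeat_class = fields[10]
                except (IndexError, ValueError) as exc:
                    raise ParseError(path, i, f"malformed rm_out line: {exc}")
            else:
                try:
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    subfamily = fields[3] if len(fields) > 3 else "."
                    strand = fields[5] if len(fields) > 5 else "unknown"
                    div = 0.0
                    repeat_class = _class_from_subfamily(subfamily)
                except (IndexError, ValueError) as exc:
                    raise ParseError(path, i, f"malformed bed6 line: {exc}")
            out.append(
                RepeatAnnotation(
                    GenomeInterval(chrom, start, end, strand),
                    repeat_class,
                    subfamily,
                    div,
                )
            )
    return out


def _class_from_subfamily(subfamily: str) -> str:
    s = subfamily.upper()
    if s.startswith(("L1", "LINE", "HAL")):
        return "LINE/L1" if not s.startswith("HAL") else "LINE/HAL"
    if s.startswith("SINEC") or s.startswith("SINE"):
        return "SINE/tRNA-Lys"
    return "Unknown"


def write_repeat_annotation(annos: Sequence[RepeatAnnotation], path) -> None:
    """Write annotations in the rm_out dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for a in annos:
            iv = a.interval
            strand = "C" if iv.strand == "-" else "+"
            fh.write(
                f"0\t{a.divergence_pct:.1f}\t0.0\t0.0\t{iv.chrom}\t{iv.start + 1}"
                f"\t{iv.end}\t(0)\t{strand}\t{a.subfamily}\t{a.repeat_class}\n"
            )


# ---------------------------------------------------------------------------
# variant calls

PAFTOOLS_COLUMNS = [
    "target_chrom",
    "target_start",
    "target_end",
    "query_chrom",
    "query_start",
    "query_end",
    "ref_seq",
    "alt_seq",
]


def read_variant_calls(
    path, dialect: str, sample_id: str = ""
) -> Tuple[List[StructuralVariantCall], List[SnvRecord], List[dict], int]:
    """Read pairwise variant calls, separating SVs (>=50 bp) from SNVs.

    Returns ``(svs, snvs, raw_small, n_rejected)``. ``raw_small`` retains
    records below the 50 bp size threshold that are not single-base
    substitutions (e.g. 1 bp indels); they are excluded downstream.
    ``n_rejected`` counts insertion records lacking sequence.
    """
    if dialect == "paftools_tsv":
        return _read_paftools_tsv(path, sample_id)
    if dialect == "vcf":
        return _read_vcf(path, sample_id)
    raise ValueError(f"unknown dialect {dialect!r}")


def _classify_record(
    tchrom, tstart, tend, qchrom, qstart, qend, ref, alt, sample_id,
    svs, snvs, raw_small,
) -> int:
    """Shared record triage. Returns 1 if an insertion lacked sequence."""
    ref = "" if ref in ("-", ".", "") else ref.upper()
    alt = "" if alt in ("-", ".", "") else alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        snvs.append(SnvRecord(tchrom, tstart, ref, alt))
        return 0
    # indel-like: exactly one side carries sequence
    kind = "insertion" if len(alt) > len(ref) else "deletion"
    seq = alt if kind == "insertion" else ref
    if not seq:
        return 1
    if len(seq) < MIN_SV_LEN:
        raw_small.append(
            dict(target_chrom=tchrom, target_start=tstart, kind=kind, seq=seq)
        )
        return 0
    svs.append(
        StructuralVariantCall(
            GenomeInterval(tchrom, tstart, tend),
            GenomeInterval(qchrom, qstart, qend),
            kind,
            seq,
            sample_id,
        )
    )
    return 0


def _read_paftools_tsv(path, sample_id):
    svs: List[StructuralVariantCall] = []
    snvs: List[SnvRecord] = []
    raw_small: List[dict] = []
    rejected = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(PAFTOOLS_COLUMNS):
                raise ParseError(path, i, f"expected {len(PAFTOOLS_COLUMNS)} columns, got {len(f)}")
            try:
                rejected += _classify_record(
                    f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]),
                    f[6], f[7], sample_id, svs, snvs, raw_small,
                )
            except ValueError as exc:
                raise ParseError(path, i, str(exc))
    return svs, snvs, raw_small, rejected


def _read_vcf(path, sample_id):
    import pysam

    svs: List[StructuralVariantCall] = []
    snvs: List[SnvRecord] = []
    raw_small: List[dict] = []
    rejected = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            ref = rec.ref or ""
            for alt in rec.alts or ():
                if alt.startswith("<"):
                    rejected += 1  # symbolic ALT: no sequence available
                    continue
                if len(ref) == 1 and len(alt) == 1:
                    snvs.append(SnvRecord(rec.chrom, rec.pos - 1, ref, alt))
                    continue
                # VCF pads indels with one anchor base
                if len(alt) > len(ref):
                    kind, seq = "insertion", alt[len(ref):]
                else:
                    kind, seq = "deletion", ref[len(alt):]
                if len(seq) < MIN_SV_LEN:
                    raw_small.append(
                        dict(target_chrom=rec.chrom, target_start=rec.pos - 1, kind=kind, seq=seq)
                    )
                    continue
                tstart = rec.pos  # first base after the anchor, 0-based
                tend = tstart if kind == "insertion" else tstart + len(seq)
                svs.append(
                    StructuralVariantCall(
                        GenomeInterval(rec.chrom, tstart, tend),
                        GenomeInterval(rec.chrom, tstart, tstart),
                        kind,
                        seq.upper(),
                        sample_id,
                    )
                )
    return svs, snvs, raw_small, rejected


def write_variant_calls(
    svs: Sequence[StructuralVariantCall], snvs: Sequence[SnvRecord], path
) -> None:
    """Write calls in the paftools_tsv dialect (8 documented columns)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAFTOOLS_COLUMNS) + "\n")
        for s in snvs:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.chrom}\t{s.pos}\t{s.pos + 1}"
                f"\t{s.ref}\t{s.alt}\n"
            )
        for v in svs:
            ref = v.inserted_seq if v.kind == "deletion" else "-"
            alt = v.inserted_seq if v.kind == "insertion" else "-"
            fh.write(
                f"{v.target.chrom}\t{v.target.start}\t{v.target.end}"
                f"\t{v.query.chrom}\t{v.query.start}\t{v.query.end}\t{ref}\t{alt}\n"
            )


# ---------------------------------------------------------------------------
# BED / FASTA / locus tables


def read_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            try:
                out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(path, i, f"malformed BED line: {exc}")
    return out


def write_bed(ivs_by_chrom: Dict[str, Iterable[Tuple[int, int]]], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ivs_by_chrom):
            for s, e in sorted(ivs_by_chrom[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\n")


def write_fasta(seqs: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_locus_table(loci: Sequence[DimorphicLocus], path) -> None:
    """TSV with the fixed documented column order; round-trips losslessly."""
    with open(path, "w") as fh:
        fh.write("\t".join(LOCUS_COLUMNS) + "\n")
        for loc in loci:
            row = []
            for col in LOCUS_COLUMNS:
                v = getattr(loc, col)
                if isinstance(v, bool):
                    v = "1" if v else "0"
                row.append(str(v))
            fh.write("\t".join(row) + "\n")


def read_locus_table(path) -> List[DimorphicLocus]:
    loci: List[DimorphicLocus] = []
    field_types = {f.name: f.type for f in dataclasses.fields(DimorphicLocus)}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != LOCUS_COLUMNS:
            raise ParseError(path, 1, "unexpected locus-table header")
        for i, line in enumerate(fh, 2):
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            if len(vals) != len(LOCUS_COLUMNS):
                raise ParseError(path, i, "wrong column count")
            kwargs = {}
            for col, raw in zip(LOCUS_COLUMNS, vals):
                t = field_types[col]
                if t in (int, "int"):
                    kwargs[col] = int(raw)
                elif t in (bool, "bool"):
                    kwargs[col] = raw == "1"
                else:
                    kwargs[col] = raw
            loci.append(DimorphicLocus(**kwargs))
    return loci


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")
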