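"""Forward simulation of a genome-assembly cohort with TPRT insertions.

The generator emulates the study design the pipeline is built for: a set
of haploid assemblies diverged along a known rooted tree from a common
ancestral genome, accumulating SNVs at a per-generation rate and gaining
SINEC/LINE-1 insertions that carry the anatomical hallmarks of
target-primed reverse transcription (target-site duplication, 3' poly(A)
tail, endonuclease-site preference, LINE-1 5' truncation and occasional
3' transduction). Confounders mirror the failure modes the real analysis
guards against: internal deletions of ancient fixed LINE-1s (which
masquerade as dimorphic insertions), biased haploid sampling of
heterozygous insertions, and exclusion regions.

Every stochastic draw flows from a single seeded generator; the emitted
truth table records, per insertion, the *realized* hallmark values (after
any chance homology extension at the junction), so exact recovery is a
well-defined contract.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_right, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import elements as el
from ._seq import call_tsd_seq, find_polya, leftmost_insert, revcomp
from .intervals import ExclusionSet, GenomeInterval
from .io_formats import (
    RepeatAnnotation,
    SnvRecord,
    StructuralVariantCall,
    write_bed,
    write_fasta,
    write_repeat_annotation,
    write_variant_calls,
)

# ---------------------------------------------------------------------------
# configuration


def default_tree() -> dict:
    """Study-shaped tree: two wolves vs (dingo, (GSD pair, Boxer/Great-Dane
    pair)); long terminal branches, short internal ones, ultrametric so all
    leaves sit 1,600 generations from the root."""
    return {
        "name": "root",
        "generations": 0,
        "children": [
            {
                "name": "wolves",
                "generations": 200,
                "children": [
                    {"name": "G_WOLF", "generations": 1400, "children": []},
                    {"name": "A_WOLF", "generations": 1400, "children": []},
                ],
            },
            {
                "name": "dogs",
                "generations": 200,
                "children": [
                    {"name": "DNG", "generations": 1400, "children": []},
                    {
                        "name": "breeds",
                        "generations": 200,
                        "children": [
                            {
                                "name": "gsd",
                                "generations": 200,
                                "children": [
                                    {"name": "GSD1", "generations": 1000, "children": []},
                                    {"name": "GSD2", "generations": 1000, "children": []},
                                ],
                            },
                            {
                                "name": "boxgdn",
                                "generations": 200,
                                "children": [
                                    {"name": "BOX", "generations": 1000, "children": []},
                                    {"name": "GDN", "generations": 1000, "children": []},
                                ],
                            },
                        ],
                    },
                ],
            },
        ],
    }


@dataclass
class SimulationConfig:
    """Parameters of the generative process.

    Rates are per generation per lineage; ``sine_rate = 1/20`` means one
    new SINEC per 20 births, the point estimate the rate module should
    recover. ``het_sampling_bias`` is the probability that a
    terminal-branch (young, plausibly heterozygous) insertion is
    represented in that sample's haploid assembly: 1.0 models an assembly
    that faithfully carries the sampled haplotype, 0.5 unbiased haploid
    sampling of heterozygous sites, lower values a biased assembler.
    """

    tree: dict = field(default_factory=default_tree)
    outgroup: str = "G_WOLF"
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    mu: float = 4.5e-9
    sine_rate: float = 1.0 / 20.0
    line_rate: float = 1.0 / 150.0
    internal_deletion_rate: float = 1.0 / 600.0
    tsd_len_range: Tuple[int, int] = (5, 20)  # uniform, inclusive
    polya_mean: float = 25.0  # geometric
    polya_min: int = 5
    truncation_full_prob: float = 0.25
    truncation_range: Tuple[float, float] = (0.1, 0.95)
    transduction_prob: float = 0.15
    transduction_len_range: Tuple[int, int] = (40, 400)
    transduction_parented_prob: float = 0.3
    transduction_min_element: int = 1500  # readthrough requires a long 3'-intact copy
    en_site_bias: float = 1.0
    het_sampling_bias: float = 1.0
    exclusion_density: float = 0.01
    n_exclusion_blocks: int = 8
    n_ancestral_line1: int = 12
    n_ancestral_sinec: int = 40
    n_ancestral_hal: int = 4
    min_event_spacing: int = 2500
    end_margin: int = 1500
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.transduction_prob,
            self.transduction_parented_prob,
            self.en_site_bias,
            self.het_sampling_bias,
            self.exclusion_density,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for r in (self.mu, self.sine_rate, self.line_rate, self.internal_deletion_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        gens = [g for _, _, g in iter_branches(self.tree)]
        if any(g < 0 for g in gens):
            raise ValueError("branch generation counts must be >= 0")
        if not gens or sum(gens) == 0:
            raise ValueError("tree has no generations (zero-length root)")
        total = sum(self.chrom_lengths.values())
        expected_bp = (
            sum(gens)
            * (self.sine_rate * 250 + self.line_rate * 4000)
        )
        if expected_bp > 0.5 * total:
            raise ValueError("insertion rates overflow the genome length")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("tsd_len_range", "truncation_range", "transduction_len_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def iter_branches(tree: dict, parent: Optional[str] = None):
    """Yield ``(parent_name, node, generations)`` for every non-root edge."""
    for child in tree.get("children", []):
        yield tree["name"], child, child["generations"]
        yield from iter_branches(child, tree["name"])


def leaves_below(node: dict) -> List[str]:
    if not node.get("children"):
        return [node["name"]]
    out: List[str] = []
    for c in node["children"]:
        out.extend(leaves_below(c))
    return out


def tree_leaves(tree: dict) -> List[str]:
    return leaves_below(tree)


def root_paths(tree: dict) -> Dict[str, List[str]]:
    """Leaf -> list of branch (child-node) names on the root-to-leaf path."""
    paths: Dict[str, List[str]] = {}

    def walk(node, acc):
        acc = acc + ([node["name"]] if node.get("_isbranch") else [])
        if not node.get("children"):
            paths[node["name"]] = acc
        for c in node["children"]:
            c["_isbranch"] = True
            walk(c, acc)
            del c["_isbranch"]

    walk(tree, [])
    return paths


# ---------------------------------------------------------------------------
# truth records and events


@dataclass
class TruthRecord:
    event_id: str
    branch: str
    sample_set: FrozenSet[str]
    element_class: str  # LINE1 | SINEC
    subfamily: str
    chrom: str
    site: int  # ancestral nick coordinate (as drawn)
    eff_site: int  # leftmost-representation breakpoint
    drawn_tsd_len: int
    tsd_seq: str  # realized duplication (chance extensions folded in)
    polya_len: int  # realized eligible tail-run length
    polya_gap: int
    orientation: str
    truncation_fraction: float
    insert_len: int
    transduction_seq: str = ""
    transduction_source: Optional[Tuple[str, int, int]] = None
    transduction_parented: bool = False
    is_het_in_assembly: bool = False

    @property
    def insertion_site(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.eff_site, self.eff_site, self.orientation)


@dataclass
class _Event:
    event_id: str
    branch: str
    chrom: str
    kind: str  # "insertion" | "internal_deletion"
    site: int  # insertion anchor, or deletion start
    tsd_len: int = 0
    block: str = ""  # oriented inserted block (element + tails), TSD excluded
    del_end: int = 0
    truth: Optional[TruthRecord] = None
    host_annotation: Optional[int] = None  # index of deleted ancestral element
    anno_span: Optional[Tuple[int, int]] = None  # element+tail span within t+block
    subfamily: str = ""
    orientation: str = "+"

    @property
    def added(self) -> int:
        return self.tsd_len + len(self.block)


# ---------------------------------------------------------------------------
# implantation primitive


def implant_insertion(
    genome: str,
    site: int,
    element_seq: str,
    tsd_len: int,
    polya_len: int,
    orientation: str,
    chrom: str = "chr1",
    event_id: str = "event",
    branch: str = "branch",
) -> Tuple[str, TruthRecord]:
    """Insert an element by the TPRT rule and report the realized anatomy.

    The ``tsd_len`` bases 3' of the nick are duplicated so that they flank
    the inserted block; a minus-orientation insertion reverse-complements
    the block (element + A-tail), placing a T-run against the left
    duplication copy. The returned truth record stores the *effective*
    hallmark values of the realized sequence: if the junction happens to
    extend the duplication by chance homology, that longer duplication is
    the ground truth a caller should report.
    """
    if not (0 <= site and site + tsd_len <= len(genome)):
        raise ValueError("insertion site out of range")
    block = element_seq + "A" * polya_len
    if orientation == "-":
        block = revcomp(block)
    filled = genome[: site + tsd_len] + block + genome[site:]
    truth = _effective_truth(genome, site, tsd_len, block, orientation)
    rec = TruthRecord(
        event_id=event_id,
        branch=branch,
        sample_set=frozenset(),
        element_class="LINE1" if len(element_seq) > 1000 else "SINEC",
        subfamily="",
        chrom=chrom,
        site=site,
        eff_site=truth["eff_site"],
        drawn_tsd_len=tsd_len,
        tsd_seq=truth["tsd_seq"],
        polya_len=truth["polya_len"],
        polya_gap=truth["polya_gap"],
        orientation=orientation,
        truncation_fraction=0.0,
        insert_len=truth["insert_len"],
    )
    return filled, rec


def _effective_truth(genome: str, site: int, tsd_len: int, block: str, orientation: str):
    """Leftmost-representation hallmarks of an implanted insertion."""
    insert0 = genome[site : site + tsd_len] + block
    ctx = genome[max(0, site - 80) : site]
    shift, insert = leftmost_insert(ctx, insert0, "")
    eff_site = site - shift
    empty_right = genome[eff_site : eff_site + len(insert) + 10]
    tsd = call_tsd_seq(insert, empty_right)
    region = insert[len(tsd) :]
    polya_len, polya_gap = find_polya(region, orientation, max_gap=5, min_len=1)
    return dict(
        eff_site=eff_site,
        tsd_seq=tsd,
        polya_len=polya_len,
        polya_gap=polya_gap,
        insert_len=len(insert),
    )


# ---------------------------------------------------------------------------
# occupied-site registry


class _Registry:
    """Sorted non-overlapping reserved intervals per chromosome."""

    def __init__(self):
        self._ivs: Dict[str, List[Tuple[int, int]]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        ivs = self._ivs.get(chrom, [])
        i = bisect_right(ivs, (end, float("inf"))) - 1
        for k in (i, i - 1):
            if 0 <= k < len(ivs) and ivs[k][0] < end and ivs[k][1] > start:
                return True
        return False

    def add(self, chrom: str, start: int, end: int) -> None:
        ivs = self._ivs.setdefault(chrom, [])
        insort(ivs, (max(0, start), end))
        merged: List[Tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self._ivs[chrom] = merged


# ---------------------------------------------------------------------------
# coordinate maps


class CoordinateMap:
    """Project ancestral coordinates into one leaf's assembly coordinates."""

    def __init__(self, edits: Sequence[Tuple[int, int, int]]):
        # edits: (start, delta, del_end); del_end == start for insertions
        self._edits = sorted(edits)
        self._cum = []
        c = 0
        for _, d, _ in self._edits:
            c += d
            self._cum.append(c)

    def project(self, pos: int) -> int:
        i = bisect_right(self._edits, (pos, float("inf"), float("inf"))) - 1
        if i < 0:
            return pos
        start, _, del_end = self._edits[i]
        if del_end > start and pos < del_end:  # inside a deleted span
            return start + (self._cum[i - 1] if i > 0 else 0)
        return pos + self._cum[i]

    def deleted(self, pos: int) -> bool:
        i = bisect_right(self._edits, (pos, float("inf"), float("inf"))) - 1
        if i < 0:
            return False
        start, _, del_end = self._edits[i]
        return del_end > start and pos < del_end


# ---------------------------------------------------------------------------
# bundle


@dataclass
class CohortBundle:
    config: SimulationConfig
    samples: List[str]  # all leaves, outgroup included
    outgroup: str
    genomes: Dict[str, Dict[str, str]]
    annotations: Dict[str, List[RepeatAnnotation]]
    exclusions: ExclusionSet  # leaf-genome coordinates
    truth: List[TruthRecord]
    confounders: List[_Event]
    maps: Dict[str, Dict[str, CoordinateMap]]
    snv_edits: Dict[str, Dict[Tuple[str, int], str]]  # per-leaf merged SNVs
    ancestral: Dict[str, str]
    events_by_leaf: Dict[str, List[_Event]]

    @property
    def query_samples(self) -> List[str]:
        return [s for s in self.samples if s != self.outgroup]

    def chrom_lengths(self, sample: str) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genomes[sample].items()}

    def aligned_regions(self, sample: str) -> Dict[str, List[Tuple[int, int]]]:
        """Single-contig coverage of the outgroup in each comparison; the
        synthetic assemblies are fully contiguous."""
        return {c: [(0, len(s))] for c, s in self.genomes[self.outgroup].items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_json(outdir / "config.json")
        for sample in self.samples:
            write_fasta(self.genomes[sample], outdir / f"{sample}.fa")
            write_repeat_annotation(self.annotations[sample], outdir / f"{sample}.rm.out")
            write_bed(self.exclusions.per_chrom(sample), outdir / f"{sample}.exclude.bed")
        for sample in self.query_samples:
            svs, snvs = emit_variant_calls(self, sample)
            write_variant_calls(svs, snvs, outdir / f"{sample}_vs_{self.outgroup}.calls.tsv")
        truth = [
            {**dataclasses.asdict(t), "sample_set": sorted(t.sample_set)}
            for t in self.truth
        ]
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# the simulator


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    config.validate()
    rng = np.random.default_rng(config.seed)
    leaves = tree_leaves(config.tree)
    if config.outgroup not in leaves:
        raise ValueError(f"outgroup {config.outgroup!r} is not a leaf of the tree")
    paths = root_paths(config.tree)
    branches = [(parent, node, node["generations"]) for parent, node, _ in iter_branches(config.tree)]

    ancestral, anc_annos = _build_ancestral(config, rng)
    registry = _Registry()
    for chrom, L in ((c, len(s)) for c, s in ancestral.items()):
        registry.add(chrom, 0, config.end_margin)
        registry.add(chrom, L - config.end_margin, L)
    for a in anc_annos:
        registry.add(a.interval.chrom, a.interval.start - 150, a.interval.end + 150)

    exclusions_anc = _draw_exclusions(config, rng, ancestral, registry)
    motif_sites = _motif_site_index(ancestral)
    sources = _draw_transduction_sources(config, rng, ancestral, anc_annos, registry)

    snv_by_branch: Dict[str, Dict[Tuple[str, int], str]] = {}
    events: List[_Event] = []
    counter = 0
    chroms = list(ancestral)
    chrom_p = np.array([len(ancestral[c]) for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    deleted_hosts: Set[int] = set()
    for _, node, gens in branches:
        bname = node["name"]
        snv_by_branch[bname] = _draw_snvs(config, rng, ancestral, gens)
        is_terminal = not node.get("children")
        below = frozenset(leaves_below(node))
        for cls, rate in (("SINEC", config.sine_rate), ("LINE1", config.line_rate)):
            n = rng.poisson(rate * gens)
            for _ in range(n):
                counter += 1
                ev = _draw_insertion(
                    config, rng, ancestral, registry, motif_sites, sources,
                    chroms, chrom_p, cls, f"ev{counter:05d}", bname, below, is_terminal,
                )
                if ev is not None:
                    events.append(ev)
        n_del = rng.poisson(config.internal_deletion_rate * gens)
        for _ in range(n_del):
            counter += 1
            ev = _draw_internal_deletion(
                config, rng, anc_annos, registry, deleted_hosts, f"ev{counter:05d}", bname
            )
            if ev is not None:
                events.append(ev)

    return _materialize(
        config, leaves, paths, ancestral, anc_annos, exclusions_anc, events, snv_by_branch
    )


def _build_ancestral(config, rng):
    """Random background with fixed ancestral repeats spliced in."""
    ancestral: Dict[str, str] = {}
    annos: List[RepeatAnnotation] = []
    specs = (
        [(el.LINE1_CONSENSUS, el.LINE1_CLASS, None) for _ in range(config.n_ancestral_line1)]
        + [(el.SINEC_CONSENSUS, el.SINEC_CLASS, None) for _ in range(config.n_ancestral_sinec)]
        + [(el.HAL_CONSENSUS, el.HAL_CLASS, el.HAL_SUBFAMILY) for _ in range(config.n_ancestral_hal)]
    )
    rng.shuffle(specs)
    chroms = list(config.chrom_lengths)
    per_chrom: Dict[str, list] = {c: [] for c in chroms}
    sizes = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    for spec in specs:
        c = chroms[int(rng.choice(len(chroms), p=sizes / sizes.sum()))]
        per_chrom[c].append(spec)
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        items = per_chrom[chrom]
        elem_total = sum(len(s) for s, _, _ in items)
        bg_len = L - elem_total
        bg = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=bg_len).tobytes().decode()
        # spaced cut points in background coordinates
        while True:
            cuts = np.sort(
                rng.integers(config.end_margin, bg_len - config.end_margin, size=len(items))
            )
            if len(cuts) < 2 or np.all(np.diff(cuts) >= config.min_event_spacing):
                break
        pieces, prev, offset = [], 0, 0
        for cut, (seq, rclass, subfam) in zip(cuts, items):
            pieces.append(bg[prev:cut])
            start = cut + offset
            strand = "+" if rng.random() < 0.5 else "-"
            oriented = seq if strand == "+" else revcomp(seq)
            pieces.append(oriented)
            if subfam is None:
                subfam = (
                    str(rng.choice(el.LINE1_OLD_SUBFAMILIES))
                    if rclass == el.LINE1_CLASS
                    else str(rng.choice(el.SINEC_SUBFAMILIES))
                )
            annos.append(
                RepeatAnnotation(
                    GenomeInterval(chrom, start, start + len(seq), strand),
                    rclass,
                    subfam,
                    float(np.round(rng.uniform(5, 25), 1)),
                )
            )
            offset += len(seq)
            prev = cut
        pieces.append(bg[prev:])
        ancestral[chrom] = "".join(pieces)
        assert len(ancestral[chrom]) == L
    return ancestral, annos


def _draw_exclusions(config, rng, ancestral, registry):
    out: Dict[str, List[Tuple[int, int]]] = {c: [] for c in ancestral}
    total = sum(len(s) for s in ancestral.values())
    n = config.n_exclusion_blocks
    if config.exclusion_density <= 0 or n == 0:
        return out
    block = max(200, int(config.exclusion_density * total / n))
    chroms = list(ancestral)
    for _ in range(n):
        for _try in range(200):
            chrom = chroms[int(rng.integers(len(chroms)))]
            L = len(ancestral[chrom])
            s = int(rng.integers(config.end_margin, L - config.end_margin - block))
            if not registry.conflicts(chrom, s - 200, s + block + 200):
                out[chrom].append((s, s + block))
                registry.add(chrom, s - 200, s + block + 200)
                break
    return out


def _motif_site_index(ancestral):
    """Positions of canonical endonuclease motifs in the ancestral genome.

    Plus-orientation nicks want TTAAAAA starting 2 bp 5' of the nick (the
    reported minus-strand 7-mer then reads TTTTTAA); minus-orientation
    nicks want TTTTTAA ending 2 bp 3' of the duplication's right edge.
    """
    idx = {}
    for chrom, seq in ancestral.items():
        plus, minus = [], []
        for pat, store in (("TTAAAAA", plus), ("TTTTTAA", minus)):
            i = seq.find(pat)
            while i != -1:
                store.append(i)
                i = seq.find(pat, i + 1)
        idx[chrom] = (plus, minus)
    return idx


def _draw_transduction_sources(config, rng, ancestral, anc_annos, registry):
    """A small pool of 3'-flank source regions; reuse creates recurrent
    ('hot') sources. Parented sources sit immediately downstream of a fixed
    LINE-1 copy; parentless sources have no adjacent element (their parent
    is, implicitly, dimorphic and absent from every assembly)."""
    pool = []
    line1s = [
        a
        for a in anc_annos
        if a.repeat_class == el.LINE1_CLASS and a.interval.strand == "+"
    ]
    n_pool = 6
    lmax = config.transduction_len_range[1]
    for _k in range(n_pool):
        parented = bool(rng.random() < config.transduction_parented_prob and line1s)
        if parented:
            a = line1s[int(rng.integers(len(line1s)))]
            iv = a.interval
            chrom = iv.chrom
            # read-through exits the parent's 3' end; the element's own
            # registry pad covers this flank, so no conflict check here
            start = iv.end + int(rng.integers(0, 10))
        else:
            ok = False
            for _try in range(200):
                chrom = list(ancestral)[int(rng.integers(len(ancestral)))]
                L = len(ancestral[chrom])
                start = int(rng.integers(config.end_margin, L - config.end_margin - lmax))
                if not registry.conflicts(chrom, start - 100, start + lmax + 100):
                    ok = True
                    break
            if not ok:
                continue
        registry.add(chrom, start - 100, start + lmax + 100)
        pool.append(dict(chrom=chrom, start=start, strand="+", parented=parented))
    return pool


def _draw_snvs(config, rng, ancestral, gens):
    out: Dict[Tuple[str, int], str] = {}
    if gens == 0 or config.mu == 0:
        return out
    chroms = list(ancestral)
    lens = np.array([len(ancestral[c]) for c in chroms])
    total = int(lens.sum())
    n = int(rng.binomial(total * gens, config.mu))
    if n == 0:
        return out
    pos = rng.integers(0, total, size=n)
    bounds = np.cumsum(lens)
    for p in pos:
        ci = int(np.searchsorted(bounds, p, side="right"))
        local = int(p - (bounds[ci - 1] if ci else 0))
        chrom = chroms[ci]
        ref = ancestral[chrom][local]
        alt = ref
        while alt == ref:
            alt = "ACGT"[int(rng.integers(4))]
        out[(chrom, local)] = alt
    return out


def _draw_insertion(
    config, rng, ancestral, registry, motif_sites, sources,
    chroms, chrom_p, cls, event_id, branch, below, is_terminal,
):
    orientation = "+" if rng.random() < 0.5 else "-"
    tsd_len = int(rng.integers(config.tsd_len_range[0], config.tsd_len_range[1] + 1))
    subfam = (
        str(rng.choice(el.SINEC_SUBFAMILIES)) if cls == "SINEC" else el.LINE1_YOUNG_SUBFAMILY
    )
    trunc = 0.0
    transd = None
    if cls == "SINEC":
        element = el.SINEC_CONSENSUS
    else:
        if rng.random() >= config.truncation_full_prob:
            trunc = float(rng.uniform(*config.truncation_range))
        element = el.LINE1_CONSENSUS[int(trunc * len(el.LINE1_CONSENSUS)) :]
        if (
            sources
            and len(element) >= config.transduction_min_element
            and rng.random() < config.transduction_prob
        ):
            src = sources[int(rng.integers(len(sources)))]
            tlen = int(rng.integers(*config.transduction_len_range))
            s0 = src["start"]
            seq = ancestral[src["chrom"]][s0 : s0 + tlen]
            if src["strand"] == "-":
                seq = revcomp(seq)
            transd = (src, tlen, seq)
    p1 = max(config.polya_min, int(rng.geometric(1.0 / config.polya_mean)))
    if transd is not None:
        p2 = max(config.polya_min, int(rng.geometric(1.0 / config.polya_mean)))
        core = element + "A" * p1 + transd[2] + "A" * p2
        anno_len = len(element) + p1  # the annotatable element + its tail
    else:
        core = element + "A" * p1
        anno_len = len(core)
    block = core if orientation == "+" else revcomp(core)

    site = _draw_site(config, rng, ancestral, registry, motif_sites, chroms, chrom_p,
                      orientation, tsd_len, len(block))
    if site is None:
        return None
    chrom, s = site
    registry.add(chrom, s - config.min_event_spacing, s + len(block) + config.min_event_spacing)

    eff = _effective_truth(ancestral[chrom], s, tsd_len, block, orientation)
    is_het = is_terminal and rng.random() > config.het_sampling_bias
    sample_set = frozenset() if is_het else below
    truth = TruthRecord(
        event_id=event_id,
        branch=branch,
        sample_set=sample_set,
        element_class=cls,
        subfamily=subfam,
        chrom=chrom,
        site=s,
        eff_site=eff["eff_site"],
        drawn_tsd_len=tsd_len,
        tsd_seq=eff["tsd_seq"],
        polya_len=eff["polya_len"],
        polya_gap=eff["polya_gap"],
        orientation=orientation,
        truncation_fraction=trunc,
        insert_len=eff["insert_len"],
        transduction_seq=transd[2] if transd else "",
        transduction_source=(
            (transd[0]["chrom"], transd[0]["start"], transd[0]["start"] + transd[1])
            if transd
            else None
        ),
        transduction_parented=transd[0]["parented"] if transd else False,
        is_het_in_assembly=is_het,
    )
    # span of the annotatable element (+ tail) within tsd+block, 5'->3' of genome
    if orientation == "+":
        anno_span = (tsd_len, tsd_len + anno_len)
    else:
        anno_span = (tsd_len + len(block) - anno_len, tsd_len + len(block))
    return _Event(
        event_id=event_id, branch=branch, chrom=chrom, kind="insertion",
        site=s, tsd_len=tsd_len, block=block, truth=truth,
        anno_span=anno_span, subfamily=subfam, orientation=orientation,
    )


def _draw_site(config, rng, ancestral, registry, motif_sites, chroms, chrom_p,
               orientation, tsd_len, block_len):
    use_motif = rng.random() < config.en_site_bias
    for _try in range(300):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
        L = len(ancestral[chrom])
        if use_motif:
            plus, minus = motif_sites[chrom]
            cands = plus if orientation == "+" else minus
            if not cands:
                use_motif = False
                continue
            p = cands[int(rng.integers(len(cands)))]
            s = p + 2 if orientation == "+" else p + 5 - tsd_len
        else:
            s = int(rng.integers(config.end_margin, L - config.end_margin))
        if s < config.end_margin or s + tsd_len + 10 > L - config.end_margin:
            continue
        if not registry.conflicts(chrom, s - 50, s + tsd_len + block_len + 50):
            return chrom, s
        if _try > 200:
            use_motif = False  # fall back to uniform rather than loop forever
    return None


def _draw_internal_deletion(config, rng, anc_annos, registry, deleted_hosts, event_id, branch):
    """Delete an internal chunk of an ancient fixed LINE-1: downstream this
    must never be mistaken for a dimorphic LINE-1 insertion."""
    hosts = [
        (i, a)
        for i, a in enumerate(anc_annos)
        if a.repeat_class == el.LINE1_CLASS and i not in deleted_hosts
    ]
    if not hosts:
        return None
    i, a = hosts[int(rng.integers(len(hosts)))]
    iv = a.interval
    max_len = min(600, len(iv) - 400)
    if max_len < 80:
        return None
    dlen = int(rng.integers(80, max_len + 1))
    start = iv.start + int(rng.integers(150, len(iv) - dlen - 150))
    deleted_hosts.add(i)
    return _Event(
        event_id=event_id, branch=branch, chrom=iv.chrom, kind="internal_deletion",
        site=start, del_end=start + dlen, host_annotation=i,
    )


# ---------------------------------------------------------------------------
# materialization


def _materialize(config, leaves, paths, ancestral, anc_annos, exclusions_anc,
                 events, snv_by_branch):
    genomes: Dict[str, Dict[str, str]] = {}
    annotations: Dict[str, List[RepeatAnnotation]] = {}
    maps: Dict[str, Dict[str, CoordinateMap]] = {}
    snv_edits: Dict[str, Dict[Tuple[str, int], str]] = {}
    exclusions = ExclusionSet()
    events_by_leaf: Dict[str, List[_Event]] = {}

    for leaf in leaves:
        branch_set = set(paths[leaf])
        merged_snv: Dict[Tuple[str, int], str] = {}
        for b in paths[leaf]:
            merged_snv.update(snv_by_branch.get(b, {}))
        snv_edits[leaf] = merged_snv
        leaf_events = [
            e
            for e in events
            if e.branch in branch_set
            and not (e.truth is not None and e.truth.is_het_in_assembly)
        ]
        events_by_leaf[leaf] = leaf_events
        genomes[leaf] = {}
        maps[leaf] = {}
        for chrom, anc in ancestral.items():
            chrom_events = sorted(
                (e for e in leaf_events if e.chrom == chrom), key=lambda e: e.site
            )
            seq, cmap = _apply_edits(anc, merged_snv, chrom, chrom_events)
            genomes[leaf][chrom] = seq
            maps[leaf][chrom] = cmap
        annotations[leaf] = _leaf_annotations(anc_annos, leaf_events, maps[leaf])
        for chrom, ivs in exclusions_anc.items():
            for s, e in ivs:
                exclusions.add(leaf, chrom, maps[leaf][chrom].project(s), maps[leaf][chrom].project(e))

    truth = [e.truth for e in events if e.truth is not None]
    confounders = [e for e in events if e.kind == "internal_deletion"]
    return CohortBundle(
        config=config,
        samples=list(leaves),
        outgroup=config.outgroup,
        genomes=genomes,
        annotations=annotations,
        exclusions=exclusions,
        truth=truth,
        confounders=confounders,
        maps=maps,
        snv_edits=snv_edits,
        ancestral=ancestral,
        events_by_leaf=events_by_leaf,
    )


def _apply_edits(anc: str, snvs, chrom: str, chrom_events) -> Tuple[str, CoordinateMap]:
    buf = bytearray(anc, "ascii")
    for (c, pos), alt in snvs.items():
        if c == chrom:
            buf[pos] = ord(alt)
    base = bytes(buf).decode()
    pieces = []
    cursor = 0
    edits = []
    for e in chrom_events:
        if e.kind == "insertion":
            pieces.append(base[cursor : e.site + e.tsd_len])
            pieces.append(e.block)
            cursor = e.site
            edits.append((e.site, e.added, e.site))
        else:
            pieces.append(base[cursor : e.site])
            cursor = e.del_end
            edits.append((e.site, -(e.del_end - e.site), e.del_end))
    pieces.append(base[cursor:])
    return "".join(pieces), CoordinateMap(edits)


def _leaf_annotations(anc_annos, leaf_events, leaf_maps) -> List[RepeatAnnotation]:
    out: List[RepeatAnnotation] = []
    for a in anc_annos:
        iv = a.interval
        cmap = leaf_maps[iv.chrom]
        s, e = cmap.project(iv.start), cmap.project(iv.end)
        if e - s >= 20:
            out.append(RepeatAnnotation(GenomeInterval(iv.chrom, s, e, iv.strand),
                                        a.repeat_class, a.subfamily, a.divergence_pct))
    for ev in leaf_events:
        if ev.kind != "insertion":
            continue
        cmap = leaf_maps[ev.chrom]
        insert_start = cmap.project(ev.site) - ev.added
        s = insert_start + ev.anno_span[0]
        e = insert_start + ev.anno_span[1]
        rclass = el.SINEC_CLASS if ev.truth.element_class == "SINEC" else el.LINE1_CLASS
        out.append(RepeatAnnotation(
            GenomeInterval(ev.chrom, s, e, ev.orientation), rclass, ev.subfamily, 0.3
        ))
    out.sort(key=lambda a: (a.interval.chrom, a.interval.start))
    return out


# ---------------------------------------------------------------------------
# variant-call emission


def emit_variant_calls(
    bundle: CohortBundle,
    sample: str,
    jitter: int = 0,
    rng: Optional[np.random.Generator] = None,
    target: Optional[str] = None,
) -> Tuple[List[StructuralVariantCall], List[SnvRecord]]:
    """Per-pair calls (sample as query vs a target genome, by default the
    outgroup) derived from the simulation truth.

    ``jitter`` adds a uniform +/-k bp shift to both coordinates of each SV
    call, exercising the breakpoint-refinement fallback ladder; with
    jitter=0 every truth difference appears as exactly one call at the true
    coordinate.
    """
    o = target if target is not None else bundle.outgroup
    if rng is None:
        rng = np.random.default_rng(0)
    s_events = {e.event_id: e for e in bundle.events_by_leaf[sample]}
    o_events = {e.event_id: e for e in bundle.events_by_leaf[o]}
    svs: List[StructuralVariantCall] = []

    def shift() -> int:
        return int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0

    for eid, e in sorted(s_events.items()):
        if eid in o_events:
            continue
        d = shift()
        mS, mO = bundle.maps[sample][e.chrom], bundle.maps[o][e.chrom]
        if e.kind == "insertion":
            qend = mS.project(e.site)
            qstart = qend - e.added
            tpos = mO.project(e.site)
            seq = bundle.genomes[sample][e.chrom][qstart:qend]
            svs.append(StructuralVariantCall(
                GenomeInterval(e.chrom, tpos + d, tpos + d),
                GenomeInterval(e.chrom, qstart + d, qend + d),
                "insertion", seq, sample,
            ))
        else:  # sample lacks the chunk; outgroup retains it
            ts = mO.project(e.site)
            seq = bundle.genomes[o][e.chrom][ts : ts + (e.del_end - e.site)]
            qpos = mS.project(e.site)
            svs.append(StructuralVariantCall(
                GenomeInterval(e.chrom, ts + d, ts + len(seq) + d),
                GenomeInterval(e.chrom, qpos + d, qpos + d),
                "deletion", seq, sample,
            ))
    for eid, e in sorted(o_events.items()):
        if eid in s_events:
            continue
        d = shift()
        mS, mO = bundle.maps[sample][e.chrom], bundle.maps[o][e.chrom]
        if e.kind == "insertion":
            tend = mO.project(e.site)
            tstart = tend - e.added
            seq = bundle.genomes[o][e.chrom][tstart:tend]
            qpos = mS.project(e.site)
            svs.append(StructuralVariantCall(
                GenomeInterval(e.chrom, tstart + d, tend + d),
                GenomeInterval(e.chrom, qpos + d, qpos + d),
                "deletion", seq, sample,
            ))
        else:  # outgroup lacks the chunk; sample retains it
            qs = mS.project(e.site)
            seq = bundle.genomes[sample][e.chrom][qs : qs + (e.del_end - e.site)]
            tpos = mO.project(e.site)
            svs.append(StructuralVariantCall(
                GenomeInterval(e.chrom, tpos + d, tpos + d),
                GenomeInterval(e.chrom, qs + d, qs + len(seq) + d),
                "insertion", seq, sample,
            ))

    snvs: List[SnvRecord] = []
    s_snv, o_snv = bundle.snv_edits[sample], bundle.snv_edits[o]
    for key in sorted(set(s_snv) | set(o_snv)):
        chrom, pos = key
        anc = bundle.ancestral[chrom][pos]
        sb = s_snv.get(key, anc)
        ob = o_snv.get(key, anc)
        if sb == ob:
            continue
        mS, mO = bundle.maps[sample][chrom], bundle.maps[o][chrom]
        if mS.deleted(pos) or mO.deleted(pos):
            continue
        snvs.append(SnvRecord(chrom, mO.project(pos), ob, sb))
    return svs, snvs
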