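"""End-to-end orchestration of the dimorphic-element analysis.

``run_pair`` executes the full catalog -> refine -> hallmark chain for
one query/target genome pair; ``run_cohort`` runs every sample against
the common outgroup and aggregates callable regions, cross-sample locus
merging, the presence/absence phylogeny with bootstrap, per-branch
retrotransposition rates, and 3' transduction tracing. All thresholds
are named fields of :class:`PipelineConfig` so sensitivity analyses need
no code edits; the same seed always reproduces the same outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import breakpoint_refine as br
from . import cohort_share as cs
from . import hallmarks as hm
from . import phylo
from . import rates as rt
from . import sv_catalog as sv
from . import transduce as td
from .intervals import subtract_intervals
from .io_formats import DimorphicLocus, write_locus_table, write_newick
from .synthetic_cohort import CohortBundle, emit_variant_calls


@dataclass
class PipelineConfig:
    """Named thresholds of the analysis, defaulting to the published values."""

    min_sv_len: int = 50
    repeat_fraction: float = 0.7
    exclusion_window: int = 100
    flank_ladder: Tuple[int, ...] = (1000, 500, 250, 125)
    consistency_bp: int = 150
    min_insert: int = 50
    min_non_tsd: int = 30
    tsd_high_conf: int = 10
    polya_min: int = 10
    polya_max_gap: int = 5
    relaxed_tsd_min: int = 7
    merge_gap: int = 100
    include_chrx: bool = False
    het_reciprocal: float = 0.9
    mu: float = rt.MU_CANINE
    mu_low: float = rt.MU_CANINE_LOW
    mu_high: float = rt.MU_CANINE_HIGH
    bootstrap_replicates: int = 1000
    jitter: int = 0
    outgroup_rate_via: str = ""  # query pair used for the outgroup branch
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "flank_ladder" in raw:
            raw["flank_ladder"] = tuple(raw["flank_ladder"])
        return cls(**raw)


@dataclass
class PairResult:
    sample: str
    target: str
    snv_count: int
    aligned_bp: int
    loci: List[DimorphicLocus]
    cascade: Dict[str, int]
    refined: Dict[str, br.RefinedLocus] = field(default_factory=dict)

    def counts(self, kind: Optional[str] = None, element_class: Optional[str] = None,
               stringent: bool = False) -> int:
        n = 0
        for loc in self.loci:
            if kind is not None and loc.kind != kind:
                continue
            if element_class is not None and loc.element_class != element_class:
                continue
            if stringent and loc.tsd_len < 10:
                continue
            n += 1
        return n

    def report(self, mu: float = rt.MU_CANINE) -> dict:
        sinec = self.counts(element_class="SINEC")
        gens = (
            rt.genome_divergence(
                rt.RateInputs(self.snv_count, self.aligned_bp, mu=mu), mu
            )
            if self.snv_count and self.aligned_bp
            else 0.0
        )
        return {
            "sample": self.sample,
            "target": self.target,
            "snv_count": int(self.snv_count),
            "aligned_bp": int(self.aligned_bp),
            "generations": float(gens),
            "sinec_insertions_in_sample": self.counts("insertion", "SINEC"),
            "sinec_insertions_in_target": self.counts("deletion", "SINEC"),
            "line1_insertions_in_sample": self.counts("insertion", "LINE1"),
            "line1_insertions_in_target": self.counts("deletion", "LINE1"),
            "sinec_snv_ratio": (sinec / self.snv_count) if self.snv_count else 0.0,
            "cascade": dict(self.cascade),
        }


def _allowed_chroms(bundle: CohortBundle, config: PipelineConfig) -> List[str]:
    chroms = sorted(bundle.genomes[bundle.outgroup])
    if not config.include_chrx:
        chroms = [c for c in chroms if c.lower() != "chrx"]
    return chroms


def run_pair(
    bundle: CohortBundle,
    sample: str,
    config: Optional[PipelineConfig] = None,
    target: Optional[str] = None,
) -> PairResult:
    config = config or PipelineConfig()
    target = target or bundle.outgroup
    import zlib

    rng = np.random.default_rng(
        (config.seed * 1009 + zlib.crc32(sample.encode()) % 9973) % (2**31)
    )
    svs, snvs = emit_variant_calls(bundle, sample, jitter=config.jitter, rng=rng, target=target)
    cascade = {"raw_svs": len(svs)}
    allowed = _allowed_chroms(bundle, config)

    filtered = sv.filter_svs(
        svs, bundle.exclusions, allowed, target_genome=target, query_genome=sample,
        min_len=config.min_sv_len, window=config.exclusion_window,
    )
    cascade["after_filters"] = len(filtered)

    loci: List[DimorphicLocus] = []
    refined_map: Dict[str, br.RefinedLocus] = {}
    n_classified = n_refined = n_hallmarked = 0
    for i, call in enumerate(filtered):
        filled = sample if call.filled_side == "query" else target
        empty = target if filled == sample else sample
        cand = sv.classify_repeat_content(
            call, bundle.annotations[filled], filled, threshold=config.repeat_fraction
        )
        if cand.element_class == "other":
            continue
        n_classified += 1
        refined = br.refine_locus(
            cand, bundle.genomes[filled], bundle.genomes[empty],
            flank_ladder=config.flank_ladder, consistency_bp=config.consistency_bp,
            min_insert=config.min_insert, min_non_tsd=config.min_non_tsd,
        )
        if refined.qc_pass and cand.element_class == "LINE1":
            refined = br.apply_line1_fp_filters(
                refined, bundle.annotations[filled],
                content_threshold=config.repeat_fraction, min_tsd=config.tsd_high_conf,
            )
        if not refined.qc_pass:
            continue
        n_refined += 1
        profile = hm.profile_locus(refined, bundle.annotations[filled])
        if profile is None:
            continue
        n_hallmarked += 1
        locus_id = f"{sample}|{target}|{i:05d}"
        if call.filled_side == "query":
            t_chrom = call.target.chrom
            t_start = t_end = refined.refined_target_pos
            q_iv = refined.filled_interval
            q_chrom, q_start, q_end = q_iv.chrom, q_iv.start, q_iv.end
        else:
            f_iv = refined.filled_interval
            t_chrom, t_start, t_end = f_iv.chrom, f_iv.start, f_iv.end
            q_chrom = call.query.chrom
            q_start = q_end = refined.refined_target_pos
        loci.append(
            DimorphicLocus(
                locus_id=locus_id,
                sample_id=sample,
                outgroup_id=target,
                kind=call.kind,
                element_class=cand.element_class,
                target_chrom=t_chrom,
                target_start=t_start,
                target_end=t_end,
                query_chrom=q_chrom,
                query_start=q_start,
                query_end=q_end,
                insert_len=refined.insert_len,
                tsd_seq=refined.tsd_seq,
                target_site_deletion_len=refined.target_site_deletion_len,
                polya_len=profile.polya_len,
                polya_gap=profile.polya_gap,
                orientation=profile.orientation,
                en_site=profile.en_site,
                stringent_class=profile.stringent_class,
                relaxed_class=profile.relaxed_class,
                subfamily=profile.subfamily,
                flank_used=refined.flank_used,
                qc_pass=True,
                qc_reason="",
            )
        )
        refined_map[locus_id] = refined
    cascade["classified"] = n_classified
    cascade["refined"] = n_refined
    cascade["hallmarked"] = n_hallmarked

    snv_count, aligned_bp = sv.extract_snvs(
        snvs,
        bundle.aligned_regions(sample) if target == bundle.outgroup
        else {c: [(0, len(s))] for c, s in bundle.genomes[target].items()},
        bundle.exclusions.per_chrom(target),
        allowed_chroms=allowed,
    )
    return PairResult(sample, target, snv_count, aligned_bp, loci, cascade, refined_map)


@dataclass
class CohortResult:
    pairs: Dict[str, PairResult]
    callable_regions: Dict[str, List[Tuple[int, int]]]
    matrices: Dict[str, cs.PresenceMatrix]
    trees: Dict[str, dict]  # per element class: newick, supports, assignment
    sharing: Dict[str, dict]
    rate_tables: Dict[str, dict]
    transductions: dict
    merged_discarded: int

    def summary(self) -> dict:
        out = {
            "samples": sorted(self.pairs),
            "pair_reports": {s: p.report() for s, p in self.pairs.items()},
            "sharing": {
                k: {
                    "total": v["total"],
                    "singletons": v["singletons"],
                    "singleton_percent": v["singleton_percent"],
                }
                for k, v in self.sharing.items()
            },
            "rates": self.rate_tables,
            "trees": {k: v["newick"] for k, v in self.trees.items()},
            "fit_percent": {k: v["assignment"]["fit_percent"] for k, v in self.trees.items()},
            "transductions": {
                "per_locus_hits": {
                    k: len(v) for k, v in self.transductions.get("hits_by_locus", {}).items()
                },
                "n_recurrent_sources": len(
                    self.transductions.get("sources", {}).get("recurrent_sources", [])
                ),
            },
        }
        return out


def run_cohort(bundle: CohortBundle, config: Optional[PipelineConfig] = None) -> CohortResult:
    config = config or PipelineConfig()
    outgroup = bundle.outgroup
    queries = bundle.query_samples
    pairs = {s: run_pair(bundle, s, config) for s in queries}

    # callable regions: single-contig coverage in every comparison minus
    # outgroup exclusions
    coverage = {s: bundle.aligned_regions(s) for s in queries}
    callable_regions = cs.compute_callable(
        coverage, bundle.exclusions.per_chrom(outgroup), _allowed_chroms(bundle, config)
    )
    chrom_lengths = {
        c: len(s)
        for c, s in bundle.genomes[outgroup].items()
        if c in set(_allowed_chroms(bundle, config))
    }

    all_loci = [loc for p in pairs.values() for loc in p.loci]
    all_loci = cs.filter_to_callable(all_loci, callable_regions, chrom_lengths)

    matrices: Dict[str, cs.PresenceMatrix] = {}
    trees: Dict[str, dict] = {}
    sharing: Dict[str, dict] = {}
    discarded_total = 0
    for cls in ("SINEC", "LINE1"):
        cls_loci = [l for l in all_loci if l.element_class == cls]
        merged, discarded = cs.merge_loci(cls_loci, bundle.samples, outgroup, gap=config.merge_gap)
        discarded_total += discarded
        if not merged:
            continue
        matrix = cs.presence_matrix(merged, bundle.samples)
        matrices[cls] = matrix
        sharing[cls] = cs.sharing_profile(matrix)
        tree, supports = phylo.bootstrap_support(
            matrix, replicates=config.bootstrap_replicates, seed=config.seed
        )
        rooted = phylo.RootedTree.from_unrooted(tree, cs.ANCESTOR)
        assignment = phylo.assign_loci_to_branches(matrix, rooted)
        trees[cls] = {
            "newick": tree.newick(cs.ANCESTOR, supports),
            "supports": {",".join(sorted(k)): v for k, v in supports.items()},
            "assignment": assignment,
        }

    rate_tables = {
        cls: _rate_table(bundle, pairs, config, cls) for cls in ("SINEC", "LINE1")
    }
    transductions = _trace_transductions(bundle, pairs, config)
    return CohortResult(
        pairs=pairs,
        callable_regions=callable_regions,
        matrices=matrices,
        trees=trees,
        sharing=sharing,
        rate_tables=rate_tables,
        transductions=transductions,
        merged_discarded=discarded_total,
    )


def _rate_table(bundle, pairs, config, element_class) -> dict:
    """Per-branch denominators: each sample branch from its own comparison
    (insertions present in the sample, absent in the outgroup); the
    outgroup branch once, via the deletion-type loci of one designated
    comparison."""
    rows: List[rt.BranchRate] = []
    via = config.outgroup_rate_via or sorted(pairs)[0]
    for sample, p in sorted(pairs.items()):
        gens = rt.genome_divergence(
            rt.RateInputs(p.snv_count, p.aligned_bp, mu=config.mu,
                          mu_low=config.mu_low, mu_high=config.mu_high)
        )
        count = p.counts("insertion", element_class)
        stringent = p.counts("insertion", element_class, stringent=True)
        rows.append(rt.BranchRate(
            branch=sample, snv_count=p.snv_count, aligned_bp=p.aligned_bp,
            generations=gens, insertion_count=count, stringent_count=stringent,
            n_all=gens / count if count else None,
            n_stringent=gens / stringent if stringent else None,
        ))
    p = pairs[via]
    gens = rt.genome_divergence(
        rt.RateInputs(p.snv_count, p.aligned_bp, mu=config.mu,
                      mu_low=config.mu_low, mu_high=config.mu_high)
    )
    count = p.counts("deletion", element_class)
    stringent = p.counts("deletion", element_class, stringent=True)
    rows.append(rt.BranchRate(
        branch=bundle.outgroup, snv_count=p.snv_count, aligned_bp=p.aligned_bp,
        generations=gens, insertion_count=count, stringent_count=stringent,
        n_all=gens / count if count else None,
        n_stringent=gens / stringent if stringent else None,
    ))
    return rt.cohort_rate_table(rows, config.mu, config.mu_low, config.mu_high)


def _trace_transductions(bundle, pairs, config) -> dict:
    outgroup = bundle.outgroup
    out_genome = bundle.genomes[outgroup]
    allowed = set(_allowed_chroms(bundle, config))
    hits_by_locus: Dict[str, List[td.TransductionHit]] = {}
    eligible = 0
    for sample, p in sorted(pairs.items()):
        for loc in p.loci:
            if loc.element_class != "LINE1":
                continue
            refined = p.refined.get(loc.locus_id)
            if refined is None:
                continue
            filled = sample if loc.kind == "insertion" else outgroup
            cand = td.extract_candidate(
                refined, bundle.annotations[filled], loc.locus_id, loc.target_start
            )
            if cand is None:
                continue
            cand = td.mask_low_complexity(cand)
            if cand is None:
                continue
            eligible += 1
            hits = td.search_genome(cand, out_genome, allowed_chroms=allowed)
            if hits:
                hits_by_locus[loc.locus_id] = hits
    positions = {
        loc.locus_id: (loc.target_chrom, loc.target_start)
        for p in pairs.values()
        for loc in p.loci
    }
    sources = td.classify_sources(
        hits_by_locus, bundle.annotations[outgroup], locus_positions=positions
    )
    return {"eligible": eligible, "hits_by_locus": hits_by_locus, "sources": sources}


def write_cohort_outputs(result: CohortResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, p in result.pairs.items():
        write_locus_table(p.loci, outdir / f"loci_{sample}.tsv")
    for cls, matrix in result.matrices.items():
        cs.write_presence_matrix(matrix, outdir / f"presence_{cls}.tsv")
    for cls, tree in result.trees.items():
        write_newick(tree["newick"], outdir / f"tree_{cls}.nwk")
    (outdir / "summary.json").write_text(json.dumps(result.summary(), indent=2, default=str))
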