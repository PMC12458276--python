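"""SNV-calibrated retrotransposition-rate estimation.

The number of generations separating a sample from the outgroup is
inferred from the autosomal SNV count, the aligned autosomal length, and
a per-generation single-nucleotide mutation rate:

    generations = SNV_count * 0.5 / (aligned_bp * mu)

(the factor 0.5 halves the two-lineage path). The per-birth insertion
rate is then expressed as a denominator N ("one insertion per N
births"): N = generations / insertion_count. Because generations scale
as 1/mu while counts are fixed, an estimate made at the point mutation
rate rescales linearly onto the rate's confidence bounds. Canine
defaults follow the wolf-pedigree estimate mu = 4.5e-9 per bp per
generation (CI 2.6e-9 - 7.1e-9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from .cohort_share import round_percent
from .intervals import overlap_len

MU_CANINE = 4.5e-9
MU_CANINE_LOW = 2.6e-9
MU_CANINE_HIGH = 7.1e-9


def round1(x: float) -> float:
    """One-decimal half-up rounding, the printed-rate convention."""
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class RateInputs:
    snv_count: int
    aligned_bp: int
    mu: float = MU_CANINE
    mu_low: float = MU_CANINE_LOW
    mu_high: float = MU_CANINE_HIGH
    insertion_count: int = 0
    stringent_insertion_count: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.mu_low <= self.mu <= self.mu_high):
            raise ValueError("mutation-rate bounds must bracket the point rate")
        if self.snv_count < 0 or self.insertion_count < 0:
            raise ValueError("counts must be >= 0")
        if self.aligned_bp <= 0:
            raise ValueError("aligned_bp must be positive")


@dataclass
class RateEstimate:
    generations: float
    births_per_insertion: float
    bounds: Tuple[float, float]  # (at mu_low, at mu_high)


@dataclass
class DemographyParams:
    Ne: float

    def __post_init__(self) -> None:
        if self.Ne < 0:
            raise ValueError("Ne must be >= 0")


def genome_divergence(inputs: RateInputs, mu_used: Optional[float] = None) -> float:
    """Generations since divergence implied by the SNV density."""
    mu = inputs.mu if mu_used is None else mu_used
    return inputs.snv_count * 0.5 / (inputs.aligned_bp * mu)


def insertion_rate(generations: float, insertion_count: int) -> float:
    """The denominator N of "one insertion per N births"."""
    if insertion_count <= 0:
        raise ValueError("insertion_count must be positive")
    return generations / insertion_count


def rescale_rate_bounds(point_n: float, mu: float, mu_bound: float) -> float:
    """N at a mutation-rate bound: generations scale as 1/mu, counts fixed."""
    if mu_bound <= 0:
        raise ValueError("mu_bound must be positive")
    return point_n * mu / mu_bound


def estimate(inputs: RateInputs, stringent: bool = False) -> RateEstimate:
    count = inputs.stringent_insertion_count if stringent else inputs.insertion_count
    gens = genome_divergence(inputs)
    n = insertion_rate(gens, count)
    return RateEstimate(
        generations=gens,
        births_per_insertion=n,
        bounds=(
            rescale_rate_bounds(n, inputs.mu, inputs.mu_low),
            rescale_rate_bounds(n, inputs.mu, inputs.mu_high),
        ),
    )


def heterozygous_fraction(
    dimorphic: Sequence[Tuple[str, int, int]],
    het_deletions: Sequence[Tuple[str, int, int]],
    reciprocal: float = 0.9,
) -> Tuple[int, float]:
    """Dimorphic loci heterozygous in the assembly's donor.

    A locus counts when some deletion call overlaps it with >= 90 %
    reciprocal overlap (overlap covers >= 90 % of the locus AND >= 90 %
    of the deletion). Returns ``(count, percent)`` with the percentage at
    0.1 precision.
    """
    from bisect import bisect_left, bisect_right

    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in het_deletions:
        by_chrom.setdefault(chrom, []).append((s, e))
    max_del: Dict[str, int] = {}
    for chrom, dels in by_chrom.items():
        dels.sort()
        max_del[chrom] = max(de - ds for ds, de in dels)
    count = 0
    for chrom, s, e in dimorphic:
        llen = e - s
        dels = by_chrom.get(chrom)
        if llen <= 0 or not dels:
            continue
        # a reciprocal overlap needs the deletion to start within reach
        lo = bisect_left(dels, (s - max_del[chrom], -1))
        hi = bisect_right(dels, (e, float("inf")))
        for ds, de in dels[lo:hi]:
            ov = overlap_len((s, e), (ds, de))
            if ov >= reciprocal * llen and ov >= reciprocal * (de - ds):
                count += 1
                break
    return count, round_percent(count, len(dimorphic))


def expected_pairwise_coalescence(dem: DemographyParams) -> float:
    """Expected coalescence time of two lineages: 2 Ne generations."""
    return 2.0 * dem.Ne


def rescale_published_rate(
    published_n: float,
    kind: str,
    old_calib: float,
    new_calib: float,
) -> float:
    """Recalibrate a published per-birth denominator to a new constant.

    Pedigree rates are direct observations and pass through unchanged.
    Phylogenetic rates scale with the assumed SNV mutation rate
    (N' = N * mu_old / mu_new); population-model rates scale with the
    assumed effective population size (N' = N * Ne_new / Ne_old).
    """
    if kind == "pedigree":
        return published_n
    if kind == "phylogeny":
        return published_n * old_calib / new_calib
    if kind == "population_model":
        return published_n * new_calib / old_calib
    raise ValueError(f"unknown estimate kind {kind!r}")


@dataclass
class BranchRate:
    branch: str
    snv_count: int
    aligned_bp: int
    generations: float
    insertion_count: int
    stringent_count: int
    n_all: Optional[float]
    n_stringent: Optional[float]


def cohort_rate_table(
    per_branch: Sequence[BranchRate], mu: float = MU_CANINE,
    mu_low: float = MU_CANINE_LOW, mu_high: float = MU_CANINE_HIGH,
) -> dict:
    """Cohort summary: arithmetic mean of the per-branch denominators (the
    outgroup branch enters once, via its single informative comparison)."""
    def _mean(vals: List[float]) -> Optional[float]:
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    out = {"branches": [], "mu": mu, "mu_low": mu_low, "mu_high": mu_high}
    for b in per_branch:
        out["branches"].append(vars(b).copy())
    for key in ("n_all", "n_stringent"):
        mean = _mean([getattr(b, key) for b in per_branch])
        out[f"mean_{key}"] = mean
        if mean is not None:
            out[f"mean_{key}_bounds"] = (
                rescale_rate_bounds(mean, mu, mu_low),
                rescale_rate_bounds(mean, mu, mu_high),
            )
    out["mean_generations"] = _mean([b.generations for b in per_branch])
    return out
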