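# Methods

## The analysis in brief

`retrodiff` estimates how often new LINE-1 and SINEC retrotransposon
insertions arise in canids, using nothing but haploid genome assemblies.
Each sample assembly is compared against a common outgroup assembly;
insertion/deletion calls ≥ 50 bp are filtered, classified by repeat
content, breakpoint-refined, and screened for the anatomical hallmarks of
target-primed reverse transcription (TPRT). The SNV count of the same
comparison calibrates time:

    generations = SNV_count × 0.5 / (aligned_bp × μ)

with μ the per-bp per-generation SNV rate (canine default 4.5×10⁻⁹,
CI 2.6×10⁻⁹–7.1×10⁻⁹, from wolf pedigree sequencing). The per-birth
insertion rate is expressed as a denominator N = generations /
insertion_count ("one insertion per N births"). Because generations scale
as 1/μ while counts are fixed, N rescales linearly onto the μ bounds.

Presence/absence of merged loci across samples (plus an all-absent
ancestor pseudo-sample) feeds a p-distance neighbor-joining tree with
bootstrap; 3′ transduced tails of LINE-1 insertions are traced back to
their source elements in the outgroup.

## The synthetic cohort

Real multi-gigabase assemblies are not tractable on a desk, so every
stage is exercised against a forward simulator with complete ground
truth. The generator's defaults emulate the study design at 1/300 scale:

* seven leaves on a rooted, ultrametric tree — two wolves as one pair
  (the outgroup among them), a dingo, and two breed-dog pairs — with long
  terminal branches (1,000–1,400 generations) and short internal ones
  (200), every leaf 1,600 generations from the root;
* a 10 Mb ancestral genome (2 autosomes) carrying fixed ancestral LINE-1,
  SINEC and HAL copies;
* SNVs per branch ~ Binomial(L·generations, μ) with μ = 4.5×10⁻⁹;
* insertions per branch ~ Poisson(rate·generations) with
  sine_rate = 1/20 and line_rate = 1/150 births — the rates the pipeline
  should recover.

Each insertion follows the TPRT anatomy: the `tsd_len` bases 3′ of the
nick are duplicated around the inserted block; the block is the element
consensus (SINEC 200 bp; LINE-1 6 kb, 5′-truncated in 75 % of copies)
plus a poly(A) tail; minus-orientation blocks are reverse-complemented so
a T-run abuts the left duplication copy. With probability
`en_site_bias` (default 1) the site is drawn from positions whose
flanking 7-mer matches the canonical endonuclease site 5′-TTTTT/AA; a
fraction of long 3′-intact LINE-1s carry a transduced tail copied from
downstream of a source position (a small reusable pool, some adjacent to
fixed "parent" LINE-1s, some parentless). Confounders: internal deletions
of ancestral LINE-1s (which pairwise comparison misreports as dimorphic
LINE-1s), exclusion regions (1 % of the genome), optional breakpoint
jitter, and a haploid-sampling parameter that omits terminal-branch
insertions from an assembly with probability 1 − het_sampling_bias.

Truth records store the *realized* hallmark values: if the junction
happens to extend the duplication by chance homology (e.g. the element's
first base equals the base after the duplication), the longer duplication
is the ground truth a caller should report. Exact recovery is therefore a
well-defined, testable contract.

Assumptions the generator does not relax (and what passing tests
therefore do not show): haploid, recombination-free genomes with neutral
insertions; a single consensus per element family (no subfamily sequence
divergence, no twin-priming rearrangements); exact single-contig
assemblies (no gaps, mis-joins or base errors beyond simulated SNVs);
insertion sites at least 2,500 bp apart and clear of exclusion regions
and ancestral elements, so each locus refines inside clean flanks.
TSD/poly(A)/truncation length distributions are not constrained by data:
TSD ~ uniform 5–20 bp, poly(A) ~ geometric(mean 25, floor 5), truncation
~ 25 % full-length else uniform fraction 0.1–0.95 — configurable, and
stated here as assumptions.

## Conventions and numerical choices

* **Coordinates** are 0-based half-open everywhere; RepeatMasker `.out`
  (1-based inclusive, strand `C`) and VCF are converted at the boundary.
* **Leftmost representation.** An insertion breakpoint is slid left while
  the last inserted base equals the base 5′ of the breakpoint. The TSD is
  the longest exact common prefix of the inserted block and the
  empty-site sequence 3′ of the breakpoint (equivalently: exact three-way
  identity of both filled-site copies and the empty site). A consequence
  worth knowing: after canonicalization the base immediately 3′ of the
  effective duplication can never equal the adjacent tail base, so
  EN-site logos from unbiased simulations are *not* column-uniform at the
  conditioned positions even though the genome is random.
* **Split alignment.** Filled and empty alleles are compared with
  prefix/suffix identity scores (match +1, mismatch −1). Score-optimal
  boundaries are contracted to the end of an exact 8 bp match run —
  without this, a mismatch followed by chance matches misplaces ~5 % of
  breakpoints by 1–3 bp. When suffix identity is weak (< 0.6 of the
  flank), the right-flank registration is re-scanned over ±50 bp; this is
  what makes target-site deletions callable under an otherwise ungapped
  model and bounds the largest callable deletion at 50 bp. If the refined
  breakpoint sits > 150 bp from its anchor, refinement re-anchors and
  retries with flanks 500, 250, 125; two consecutive agreeing refinements
  are accepted, otherwise the locus fails QC (`discordant`). Flanks may
  clip to 50 bp at contig ends; below that the locus fails QC.
* **Poly(A).** Longest orientation-appropriate homopolymer in the
  between-TSD region with gap ≤ 5 bp to the element's 3′ boundary
  (measured to the called TSD's inner edge whenever any TSD exists, else
  the insert boundary); reported at ≥ 10 bp; ties go to the run nearer
  the boundary. Relaxed mode instead accepts any 15 bp window with ≥ 10
  matching bases within 30 bp of the boundary, scanned at stride 1, and
  lowers the TSD floor to 7 bp.
* **EN site.** Reported as a 7-mer on the minus strand (canonical
  TTTTTAA), requiring TSD ≥ 10 and a defined orientation; the
  minus-orientation case mirrors the plus-orientation definition at the
  downstream TSD copy so both orientations superimpose in a logo.
* **Merging.** Pairwise loci are single-linkage clustered at ≤ 100 bp in
  outgroup coordinates; a cluster is one variant only if members agree in
  kind and element class and no sample contributes two calls.
  Deletion-type loci (element fixed in the outgroup) are present in the
  outgroup and every non-calling sample. The presence matrix is
  autosome-only by default (chrX via a flag).
* **Neighbor joining** is the classic Saitou–Nei agglomeration with
  deterministic tie-breaking (smallest Q, then lexicographic indices);
  negative branch lengths are clamped to zero with the deficit shifted to
  the sister edge. Bootstrap resamples loci with replacement; supports
  are per-bipartition percentages annotated on the full-data tree, which
  is rooted on the ancestor leaf. The ancestor row participates in
  distances and rooting but never in branch assignment.
* **Rates.** Per-branch denominators use each sample's own comparison
  (element present in sample, absent in outgroup); the outgroup branch
  enters once, through the deletion-type loci of one designated
  comparison. The cohort summary is the arithmetic mean of per-branch
  denominators. Stringent estimates restrict to TSD ≥ 10 bp loci and are
  therefore upper bounds on N by construction. Printed-style rounding is
  one decimal, half-up.
* **Transductions.** Candidates run from the longest intersecting LINE-1
  annotation's 3′ end to the between-TSD region's 3′ boundary (read in
  element orientation); ≥ 25 bp required before and after DUST-style
  masking (window 64, threshold 20, repeated-triplet positions masked).
  The search is deterministic seed-and-extend: 11-mer exact seeds at
  stride 5, two consistently-placed seeds required per candidate window,
  edit-distance extension; hits need ≥ 95 % identity, ≥ 25 matched bases,
  a span within 100 bp of the query, > 10 kb from the locus itself; a
  candidate with > 50 placements and a locus with > 5 surviving hits are
  voided. Parent adjacency = a LINE-1 annotation within 50 bp whose 3′
  end lies upstream of the hit in concordant orientation. Sources merged
  at ≤ 100 bp; recurrence requires more than one *independent* insertion
  (loci within the merge gap in outgroup coordinates collapse first).

## Scaled-down problem sizes

The default cohort (7 samples × 10 Mb, ≈ 500 insertions, ≈ 60 LINE-1s)
is the package's standard validation scenario: it runs the entire
analysis — six pairwise comparisons, merging, 1,000-bootstrap trees for
both element classes, rates, transduction tracing — in well under a
minute, while containing enough internal-branch loci (~10 per internal
edge) that true clades attract ≥ 95 % support. Parameter recovery uses a
two-leaf tree (4,000 generations per branch, 2 × 3 Mb) over ten seeds;
with ~200 SNVs and ~200 SINEC insertions per side, the per-seed
denominator has ~10 % sampling error and the ten-seed mean recovers the
generative 1/20 and 1/150 within three standard errors.

## Known limitations

* The split aligner handles one variant per locus and no inversions or
  translocations; twin-priming-rearranged LINE-1s would pass through
  without poly(A) calls.
* The exact-match TSD contract is stricter than a mismatch-tolerant
  aligner; degraded duplications in diverged genomes under-count TSDs
  (an optional ≤ 1-mismatch flag exists on the junction caller, unused
  by default).
* Target-site deletions beyond 50 bp and call-length errors beyond the
  registration scan fail refinement rather than degrade silently.
* Subfamily assignment inherits whatever annotation labels are supplied;
  it resolves the SINEC_Cf/SINEC2A1_Cf ambiguity by merging the pair and
  reports conflicts as `unresolved` rather than adjudicating them.
* Rate estimates assume constant μ and insertion rates along all
  branches and neutrality of insertions; violation biases N in the same
  direction as in any phylogenetic rate estimate.
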