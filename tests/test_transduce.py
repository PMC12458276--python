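"""3' transduction candidates, masking, genome search, source tracing."""

import numpy as np
import pytest

from retrodiff._seq import revcomp
from retrodiff.breakpoint_refine import RefinedLocus
from retrodiff.intervals import GenomeInterval
from retrodiff.io_formats import RepeatAnnotation, StructuralVariantCall
from retrodiff.sv_catalog import CandidateLocus
from retrodiff.transduce import (
    TransductionCandidate,
    TransductionHit,
    classify_sources,
    dust_mask,
    extract_candidate,
    mask_low_complexity,
    search_genome,
)


def _rng_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _refined_line1(insert_seq, tsd, span_start=5000):
    span = (span_start, span_start + len(insert_seq))
    call = StructuralVariantCall(
        GenomeInterval("chr1", span_start, span_start),
        GenomeInterval("chr1", *span), "insertion", insert_seq, "S",
    )
    return RefinedLocus(
        candidate=CandidateLocus(call, "LINE1", 1.0, "S"),
        flank_used=1000, insert_seq=insert_seq, refined_target_pos=span_start,
        filled_interval=GenomeInterval("chr1", *span), tsd_seq=tsd,
        target_site_deletion_len=0, filled_left_context="", filled_right_context="",
        qc_pass=True, qc_reason="",
    )


def _anno(start, end, strand="+", subfam="L1_Cf", rclass="LINE/L1"):
    return RepeatAnnotation(GenomeInterval("chr1", start, end, strand), rclass, subfam)


class TestExtractCandidate:
    def test_short_tail_after_tsd_removal_gives_none(self):
        tsd = "T" * 12
        rng = np.random.default_rng(0)
        body = _rng_seq(rng, 200)
        tail = _rng_seq(rng, 30)
        insert = tsd + body + tail
        r = _refined_line1(insert, tsd)
        # annotation ends 30 bp before the region end: candidate 30 < 25? no,
        # 30 >= 25 -- shrink to 18 bp to hit the rule
        r18 = _refined_line1(tsd + body + tail[:18], tsd)
        anno = _anno(5000 + 12, 5000 + 12 + 200)
        assert extract_candidate(r18, [anno], "L", 5000) is None

    def test_60bp_tail_no_tsd_kept(self):
        rng = np.random.default_rng(1)
        body, tail = _rng_seq(rng, 300), _rng_seq(rng, 60)
        r = _refined_line1(body + tail, "")
        anno = _anno(5000, 5300)
        cand = extract_candidate(r, [anno], "L", 5000)
        assert cand is not None and cand.seq == tail

    def test_longest_annotation_chosen(self):
        rng = np.random.default_rng(2)
        body, tail = _rng_seq(rng, 300), _rng_seq(rng, 60)
        r = _refined_line1(body + tail, "")
        annos = [_anno(5000, 5100), _anno(5000, 5300)]
        cand = extract_candidate(r, annos, "L", 5000)
        assert cand.seq == tail

    def test_minus_element_reads_tail_in_element_orientation(self):
        rng = np.random.default_rng(3)
        tail = _rng_seq(rng, 60)
        body = _rng_seq(rng, 300)
        insert = revcomp(tail) + body  # tail genomically left of a minus element
        r = _refined_line1(insert, "")
        anno = _anno(5060, 5360, strand="-")
        cand = extract_candidate(r, [anno], "L", 5000)
        assert cand.seq == tail


class TestMasking:
    def test_homopolymer_fully_masked_and_discarded(self):
        cand = TransductionCandidate("L", "chr1", 0, "A" * 40)
        assert mask_low_complexity(cand) is None

    def test_random_sequence_kept(self):
        rng = np.random.default_rng(4)
        cand = TransductionCandidate("L", "chr1", 0, _rng_seq(rng, 40))
        assert mask_low_complexity(cand) is not None

    def test_mixed_sequence_keeps_full_seq_for_search(self):
        rng = np.random.default_rng(5)
        unique = _rng_seq(rng, 30)
        cand = TransductionCandidate("L", "chr1", 0, unique + "A" * 30)
        out = mask_low_complexity(cand)
        assert out is not None and out.seq == unique + "A" * 30
        assert out.unmasked_bp >= 25

    def test_dust_windows_match_triplet_oracle(self):
        rng = np.random.default_rng(6)
        seq = _rng_seq(rng, 64)
        masked = dust_mask(seq)
        counts = {}
        for i in range(62):
            t = seq[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = 10.0 * sum(c * (c - 1) / 2 for c in counts.values()) / 61
        assert bool(masked) == (score > 20.0)


class TestSearchGenome:
    def _genome_with_copy(self, rng, seq, at=200_000, n=500_000):
        g = _rng_seq(rng, n)
        return g[:at] + seq + g[at + len(seq):]

    def test_verbatim_copy_found_at_truth_position(self):
        rng = np.random.default_rng(7)
        seq = _rng_seq(rng, 120)
        genome = {"chr1": self._genome_with_copy(rng, seq)}
        cand = TransductionCandidate("L", "chr2", 0, seq)
        hits = search_genome(cand, genome)
        assert len(hits) == 1
        h = hits[0]
        assert h.target.chrom == "chr1" and abs(h.target.start - 200_000) <= 10
        assert h.identity >= 0.95 and h.match_bp >= 25

    def test_self_locus_suppressed_within_10kb(self):
        rng = np.random.default_rng(8)
        seq = _rng_seq(rng, 120)
        genome = {"chr1": self._genome_with_copy(rng, seq)}
        cand = TransductionCandidate("L", "chr1", 205_000, seq)
        assert search_genome(cand, genome) == []

    def test_repetitive_candidate_voided_by_hit_cap(self):
        rng = np.random.default_rng(9)
        seq = _rng_seq(rng, 60)
        g = "".join(_rng_seq(rng, 1500) + seq for _ in range(60))
        cand = TransductionCandidate("L", "chr2", 0, seq)
        assert search_genome(cand, {"chr1": g}) == []

    def test_divergent_copy_rejected_below_95_identity(self):
        rng = np.random.default_rng(10)
        seq = _rng_seq(rng, 100)
        noisy = list(seq)
        for p in rng.choice(100, 8, replace=False):  # 92 % identity
            noisy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[p]]
        genome = {"chr1": self._genome_with_copy(rng, "".join(noisy))}
        cand = TransductionCandidate("L", "chr2", 0, seq)
        assert search_genome(cand, genome) == []


class TestClassifySources:
    def _hit(self, locus, start, end, strand="+"):
        return TransductionHit(locus, GenomeInterval("chr1", start, end, strand),
                               1.0, end - start, strand)

    def test_parent_adjacent_plus_strand(self):
        hits = {"L1": [self._hit("L1", 10_000, 10_200)]}
        annos = [_anno(3_000, 9_980)]  # 3' end 20 bp upstream of the hit
        out = classify_sources(hits, annos)
        assert out["hits"][0].parent_adjacent

    def test_parentless_when_no_element_nearby(self):
        hits = {"L1": [self._hit("L1", 10_000, 10_200)]}
        annos = [_anno(50_000, 56_000)]
        out = classify_sources(hits, annos)
        assert not out["hits"][0].parent_adjacent

    def test_wrong_side_or_strand_not_adjacent(self):
        hits = {"L1": [self._hit("L1", 10_000, 10_200)]}
        # element downstream of the hit: transduction would be upstream: no
        annos = [_anno(10_220, 16_000)]
        assert not classify_sources(hits, annos)["hits"][0].parent_adjacent
        # minus-strand element on the left: its 3' end points away
        annos = [_anno(3_000, 9_980, strand="-")]
        hits = {"L1": [self._hit("L1", 10_000, 10_200)]}
        assert not classify_sources(hits, annos)["hits"][0].parent_adjacent

    def test_recurrent_source_from_two_independent_insertions(self):
        hits = {
            "A|x": [self._hit("A|x", 10_000, 10_200)],
            "B|y": [self._hit("B|y", 10_050, 10_210)],
        }
        positions = {"A|x": ("chr3", 100_000), "B|y": ("chr5", 900_000)}
        out = classify_sources(hits, [], locus_positions=positions)
        assert len(out["recurrent_sources"]) == 1

    def test_shared_variant_seen_twice_not_recurrent(self):
        hits = {
            "A|x": [self._hit("A|x", 10_000, 10_200)],
            "B|y": [self._hit("B|y", 10_000, 10_200)],
        }
        positions = {"A|x": ("chr3", 100_000), "B|y": ("chr3", 100_040)}
        out = classify_sources(hits, [], locus_positions=positions)
        assert out["recurrent_sources"] == []

    def test_locus_with_too_many_transductions_voided(self):
        hits = {"L1": [self._hit("L1", 10_000 + i * 30_000, 10_200 + i * 30_000)
                       for i in range(6)]}
        out = classify_sources(hits, [])
        assert out["hits"] == []
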