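"""Split re-alignment, TSD calling, and LINE-1 false-positive filters on
constructed toys with hand-checked expectations."""

import numpy as np
import pytest

from retrodiff.breakpoint_refine import (
    RefinedLocus,
    apply_line1_fp_filters,
    refine_locus,
)
from retrodiff.intervals import GenomeInterval
from retrodiff.io_formats import RepeatAnnotation, StructuralVariantCall
from retrodiff.sv_catalog import CandidateLocus


def _rng_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), n))


def _locus(rng, *, tsd=10, insert_core=200, site=3000, genome_len=7000,
           ts_del=0, polya=20):
    """Construct (empty, filled, expectations) with a known anatomy."""
    empty = _rng_seq(rng, genome_len)
    core = _rng_seq(rng, insert_core - 1, "ACG") + "G" + "A" * polya
    dup = empty[site : site + tsd]
    filled = empty[: site + tsd] + core + empty[site:]
    if ts_del:
        # remove ts_del bases at the junction of the *filled* allele instead:
        # empty retains D; model as empty = P + D + S vs filled = P + I + S
        filled = empty[:site] + core + empty[site + ts_del :]
        dup = ""
    return empty, filled, dup, core


def _candidate(call_pos, insert_len, jig=0, kind="insertion"):
    call = StructuralVariantCall(
        GenomeInterval("chr1", call_pos + jig, call_pos + jig),
        GenomeInterval("chr1", call_pos + jig, call_pos + jig + insert_len),
        kind, "N" * insert_len, "S",
    )
    return CandidateLocus(call, "SINEC", 1.0, "S")


class TestRefineLocus:
    def test_noise_free_coordinates_and_tsd_exact(self):
        rng = np.random.default_rng(10)
        empty, filled, dup, core = _locus(rng, tsd=12)
        cand = _candidate(3000, 12 + len(core))
        ref = refine_locus(cand, {"chr1": filled}, {"chr1": empty})
        assert ref.qc_pass and ref.flank_used == 1000
        assert ref.refined_target_pos == 3000
        assert ref.tsd_seq.startswith(dup) and len(ref.tsd_seq) >= 12
        assert ref.insert_seq == filled[ref.filled_interval.start : ref.filled_interval.end]

    def test_jitter_200_uses_500_flank_and_passes(self):
        rng = np.random.default_rng(11)
        empty, filled, dup, core = _locus(rng, tsd=12)
        base = refine_locus(_candidate(3000, 12 + len(core)),
                            {"chr1": filled}, {"chr1": empty})
        cand = _candidate(3000, 12 + len(core), jig=200)
        ref = refine_locus(cand, {"chr1": filled}, {"chr1": empty})
        assert ref.qc_pass and ref.flank_used == 500
        assert ref.refined_target_pos == base.refined_target_pos
        assert ref.tsd_seq == base.tsd_seq

    def test_short_insert_fails_qc(self):
        rng = np.random.default_rng(12)
        empty, filled, dup, core = _locus(rng, tsd=0, insert_core=45, polya=0)
        cand = _candidate(3000, len(core))
        ref = refine_locus(cand, {"chr1": filled}, {"chr1": empty})
        assert not ref.qc_pass and ref.qc_reason == "short"

    def test_low_non_tsd_fails_qc(self):
        rng = np.random.default_rng(13)
        # 55 bp insert of which 28 bp non-TSD: passes the size floor but not
        # the 30 bp non-duplicated minimum
        empty = _rng_seq(rng, 6000)
        dup = empty[3000:3027]
        core = _rng_seq(rng, 27, "CG") + "G"
        filled = empty[:3027] + core + empty[3000:]
        cand = _candidate(3000, 27 + 28)
        ref = refine_locus(cand, {"chr1": filled}, {"chr1": empty})
        assert not ref.qc_pass and ref.qc_reason == "low_non_tsd"

    def test_blunt_insertion_no_tsd_no_tsdel(self):
        rng = np.random.default_rng(14)
        empty = _rng_seq(rng, 6000, "AC")
        core = _rng_seq(rng, 120, "GT")  # disjoint alphabet: no chance homology
        filled = empty[:3000] + core + empty[3000:]
        cand = _candidate(3000, 120)
        ref = refine_locus(cand, {"chr1": filled}, {"chr1": empty})
        assert ref.qc_pass and ref.tsd_seq == "" and ref.target_site_deletion_len == 0

    def test_target_site_deletion_of_5(self):
        rng = np.random.default_rng(15)
        empty = _rng_seq(rng, 6000, "AC")
        core = _rng_seq(rng, 150, "GT")
        # empty = P + D + S; filled = P + I + S with |D| = 5
        filled = empty[:3000] + core + empty[3005:]
        cand = _candidate(3000, 150)
        ref = refine_locus(cand, {"chr1": filled}, {"chr1": empty})
        assert ref.qc_pass
        assert ref.target_site_deletion_len == 5 and ref.tsd_seq == ""

    def test_translation_invariance(self):
        rng = np.random.default_rng(16)
        empty, filled, dup, core = _locus(rng, tsd=8)
        shift = 1234
        pad = _rng_seq(np.random.default_rng(99), shift)
        ref1 = refine_locus(_candidate(3000, 8 + len(core)),
                            {"chr1": filled}, {"chr1": empty})
        ref2 = refine_locus(_candidate(3000 + shift, 8 + len(core)),
                            {"chr1": pad + filled}, {"chr1": pad + empty})
        assert ref2.refined_target_pos == ref1.refined_target_pos + shift
        assert ref2.tsd_seq == ref1.tsd_seq
        assert ref2.insert_seq == ref1.insert_seq

    def test_snv_in_flank_does_not_move_breakpoint(self):
        rng = np.random.default_rng(17)
        empty, filled, dup, core = _locus(rng, tsd=12)
        # a substitution 300 bp into the left flank of the empty allele
        pos = 2700
        empty2 = empty[:pos] + ("A" if empty[pos] != "A" else "C") + empty[pos + 1 :]
        ref = refine_locus(_candidate(3000, 12 + len(core)),
                           {"chr1": filled}, {"chr1": empty2})
        assert ref.qc_pass and ref.refined_target_pos == 3000

    def test_missing_sequence_raises(self):
        with pytest.raises(ValueError):
            refine_locus(_candidate(100, 60), {"chr2": "ACGT"}, {"chr1": "ACGT"})


def test_mismatch_tolerant_tsd_caller():
    from retrodiff._seq import call_tsd_seq

    insert = "ACGTACGTAC" + "GGGG"
    right = "ACGAACGTAC" + "TTTT"  # one substitution inside the duplication
    assert call_tsd_seq(insert, right) == "ACG"
    assert call_tsd_seq(insert, right, max_mismatch=1) == "ACGTACGTAC"
    # the duplication never ends on a mismatch
    assert call_tsd_seq("ACGT", "ACGA", max_mismatch=1) == "ACG"


def _anno(start, end, subfam="L1_Cf", rclass="LINE/L1", strand="+"):
    return RepeatAnnotation(GenomeInterval("chr1", start, end, strand), rclass, subfam)


class TestLine1FpFilters:
    def _refined(self, rng, *, tsd, anno_span, insert_span=(3000, 3600)):
        core = _rng_seq(rng, insert_span[1] - insert_span[0])
        return (
            RefinedLocus(
                candidate=_candidate(insert_span[0], len(core)),
                flank_used=1000,
                insert_seq=core,
                refined_target_pos=insert_span[0],
                filled_interval=GenomeInterval("chr1", *insert_span),
                tsd_seq="T" * tsd,
                target_site_deletion_len=0,
                filled_left_context="",
                filled_right_context="",
                qc_pass=True,
                qc_reason="",
            ),
            [_anno(*anno_span)],
        )

    def test_embedded_without_tsd_dropped(self):
        rng = np.random.default_rng(20)
        refined, annos = self._refined(rng, tsd=0, anno_span=(2000, 4500))
        out = apply_line1_fp_filters(refined, annos)
        assert not out.qc_pass and out.qc_reason == "embedded_no_tsd"

    def test_true_nested_insertion_with_tsd_retained(self):
        rng = np.random.default_rng(21)
        refined, annos = self._refined(rng, tsd=12, anno_span=(2000, 4500))
        assert apply_line1_fp_filters(refined, annos).qc_pass

    def test_low_line1_content_dropped(self):
        rng = np.random.default_rng(22)
        # annotation covers only 60 % of the insert
        refined, annos = self._refined(rng, tsd=12, anno_span=(3000, 3360))
        out = apply_line1_fp_filters(refined, annos)
        assert not out.qc_pass and out.qc_reason == "low_line1_content"

    def test_hal_annotation_does_not_rescue_content(self):
        rng = np.random.default_rng(23)
        refined, _ = self._refined(rng, tsd=12, anno_span=(3000, 3600))
        annos = [_anno(3000, 3600, subfam="HAL1", rclass="LINE/HAL")]
        out = apply_line1_fp_filters(refined, annos)
        assert not out.qc_pass and out.qc_reason == "low_line1_content"
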