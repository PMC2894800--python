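"""Consequence engine: boundary exactness, coding effects, severity ranking."""

import pytest

from varkit import consequence as cq
from varkit.io_formats import VariantRecord

from oracles import bf_consequence


def snv(pos, ref, alt, id="v"):
    return VariantRecord("chr1", pos, pos, ref, [alt], id=id)


def _label(v, t, genome):
    calls = cq.classify(v, t, genome)
    assert len(calls) >= 1
    return cq.summary_consequence(calls)


class TestSnvClasses:
    def test_second_intron_base_is_essential_splice(self, t_plus, genome):
        pos = t_plus.introns[0][1] - 1  # 2 bp from the acceptor end
        v = snv(pos, genome.base("chr1", pos), "A" if genome.base("chr1", pos) != "A" else "C")
        assert _label(v, t_plus, genome) == cq.ESSENTIAL_SPLICE_SITE

    def test_tgg_to_tga_is_stop_gained(self, t_plus, genome):
        # pinned TGG codon at 8976-8978; G>A at the third base gives TGA
        assert genome.fetch("chr1", 8_976, 8_978) == "TGG"
        call = cq.classify(snv(8_978, "G", "A"), t_plus, genome)[0]
        assert call.consequence_type == cq.STOP_GAINED
        assert (call.ref_codon, call.alt_codon) == ("TGG", "TGA")
        assert (call.ref_aa, call.alt_aa) == ("W", "*")

    def test_ctg_to_cta_is_synonymous_leucine(self, t_plus, genome):
        # pinned CTG codon at 9096-9098 (3 bp from the junction)
        call = cq.classify(snv(9_098, "G", "A"), t_plus, genome)[0]
        assert call.consequence_type == cq.SPLICE_SYNONYMOUS
        assert call.ref_aa == call.alt_aa == "L"

    def test_terminal_stop_codon_change_is_stop_lost(self, t_plus, genome):
        assert genome.fetch("chr1", 9_899, 9_901) == "TAA"
        call = cq.classify(snv(9_899, "T", "C"), t_plus, genome)[0]
        assert call.consequence_type == cq.STOP_LOST

    def test_split_codon_across_junction_translated_in_transcript_frame(
        self, t_plus, genome
    ):
        # codon spans 9099-9100 | intron | 9601: TG|G = Trp
        call = cq.classify(snv(9_100, "G", "A"), t_plus, genome)[0]
        assert call.ref_codon == "TGG"
        assert call.consequence_type == cq.STOP_GAINED_SPLICE

    def test_minus_strand_codons_use_transcript_orientation(self, t_minus, genome):
        pos = t_minus.cds_end  # first CDS base of the minus-strand transcript
        ref = genome.base("chr1", pos)
        call = cq.classify(snv(pos, ref, "A" if ref != "A" else "C"), t_minus, genome)[0]
        assert call.cds_pos == 1 and call.protein_pos == 1
        assert call.consequence_type == bf_consequence(
            pos, ref, call.allele, t_minus, genome
        )


class TestBoundaryFlips:
    """Label changes occur exactly at the documented offsets."""

    def _snv_at(self, pos, genome):
        ref = genome.base("chr1", pos)
        return snv(pos, ref, "A" if ref != "A" else "C")

    def test_intron_offset_2_to_3(self, t_plus, genome):
        s = t_plus.introns[1][0]
        assert _label(self._snv_at(s + 1, genome), t_plus, genome) == cq.ESSENTIAL_SPLICE_SITE
        assert _label(self._snv_at(s + 2, genome), t_plus, genome) == cq.SPLICE_SITE_INTRONIC

    def test_intron_offset_8_to_9(self, t_plus, genome):
        s = t_plus.introns[1][0]
        assert _label(self._snv_at(s + 7, genome), t_plus, genome) == cq.SPLICE_SITE_INTRONIC
        assert _label(self._snv_at(s + 8, genome), t_plus, genome) == cq.INTRONIC

    def test_exon_offset_3_to_4_drops_splice_modifier(self, t_plus, genome):
        exon_start = t_plus.exons[3][0]  # 3' UTR exon behind intron 3
        at3 = _label(self._snv_at(exon_start + 2, genome), t_plus, genome)
        at4 = _label(self._snv_at(exon_start + 3, genome), t_plus, genome)
        assert at3 == cq.SPLICE_UTR_3 and at4 == cq.UTR_3

    def test_upstream_flips_to_intergenic_past_5kb(self, t_plus, genome):
        at5000 = self._snv_at(t_plus.span[0] - 5_000, genome)
        at5001 = self._snv_at(t_plus.span[0] - 5_001, genome)
        assert cq.annotate([at5000], [t_plus], genome)[0].consequence_type == cq.UPSTREAM
        assert cq.annotate([at5001], [t_plus], genome)[0].consequence_type == cq.INTERGENIC

    def test_downstream_respects_transcript_orientation(self, t_minus, genome):
        # genomically before a minus-strand transcript means downstream
        v = self._snv_at(t_minus.span[0] - 100, genome)
        assert _label(v, t_minus, genome) == cq.DOWNSTREAM


class TestIndels:
    def test_two_bp_deletion_in_cds_is_frameshift(self, t_plus, genome):
        ref2 = genome.fetch("chr1", 8_950, 8_951)
        v = VariantRecord("chr1", 8_950, 8_951, ref2, [""], id="d")
        assert _label(v, t_plus, genome) == cq.FRAMESHIFT

    def test_three_bp_deletion_in_cds_is_not_frameshift(self, t_plus, genome):
        ref3 = genome.fetch("chr1", 8_950, 8_952)
        v = VariantRecord("chr1", 8_950, 8_952, ref3, [""], id="d")
        assert _label(v, t_plus, genome) == cq.NON_SYNONYMOUS

    def test_insertion_in_cds_is_frameshift(self, t_plus, genome):
        v = VariantRecord("chr1", 8_951, 8_950, "", ["T"], id="i")
        assert _label(v, t_plus, genome) == cq.FRAMESHIFT

    def test_indel_spanning_exon_intron_border_is_complex(self, t_plus, genome):
        e = t_plus.exons[1][1]  # exon 2 3' edge
        ref = genome.fetch("chr1", e - 1, e + 2)
        v = VariantRecord("chr1", e - 1, e + 2, ref, [""], id="x")
        assert _label(v, t_plus, genome) == cq.COMPLEX_INDEL

    def test_indel_spanning_cds_utr_border_is_complex(self, t_plus, genome):
        cs = t_plus.cds_start
        ref = genome.fetch("chr1", cs - 1, cs + 1)
        v = VariantRecord("chr1", cs - 1, cs + 1, ref, [""], id="x")
        assert _label(v, t_plus, genome) == cq.COMPLEX_INDEL

    def test_multiallelic_stop_gain_plus_frameshift_combines(self, t_plus, genome):
        # allele 1: G>A at pinned TGG -> stop; allele 2: G>GT insertion -> frameshift
        v = VariantRecord("chr1", 8_977, 8_977, "G", ["A", "GTT"], id="m")
        calls = cq.classify(v, t_plus, genome)
        assert [c.consequence_type for c in calls] == [cq.STOP_GAINED_FRAMESHIFT]

    def test_wholly_intronic_deletion_keeps_intron_classes(self, t_plus, genome):
        s = t_plus.introns[0][0]
        ref = genome.fetch("chr1", s + 20, s + 22)
        v = VariantRecord("chr1", s + 20, s + 22, ref, [""], id="x")
        assert _label(v, t_plus, genome) == cq.INTRONIC


class TestOtherTargets:
    def test_mature_mirna_interval(self, transcripts, genome):
        t = next(t for t in transcripts if t.id == "t_mir")
        v = snv(24_030, genome.base("chr1", 24_030), "A" if genome.base("chr1", 24_030) != "A" else "C")
        assert _label(v, t, genome) == cq.WITHIN_MATURE_MIRNA

    def test_non_coding_gene_outside_mature_interval(self, transcripts, genome):
        t = next(t for t in transcripts if t.id == "t_mir")
        v = snv(24_005, genome.base("chr1", 24_005), "A" if genome.base("chr1", 24_005) != "A" else "C")
        assert _label(v, t, genome) == cq.WITHIN_NON_CODING_GENE

    def test_regulatory_feature_adds_call(self, transcripts, genome, bundle):
        regs = bundle["regulatory"]
        pos = regs[0].start + 5
        v = snv(pos, genome.base("chr1", pos), "A" if genome.base("chr1", pos) != "A" else "C")
        calls = cq.annotate([v], transcripts, genome, regs)
        assert cq.REGULATORY_REGION in {c.consequence_type for c in calls}

    def test_variant_far_from_everything_is_intergenic(self, transcripts, genome):
        v = snv(2_000, genome.base("chr1", 2_000), "A" if genome.base("chr1", 2_000) != "A" else "C")
        calls = cq.annotate([v], transcripts, genome)
        assert [c.consequence_type for c in calls] == [cq.INTERGENIC]


class TestRanking:
    def test_severity_vocabulary_is_closed_and_total(self):
        assert len(cq.SEVERITY) == 26
        assert len(set(cq.SEVERITY)) == 26

    def test_stop_gained_outranks_intronic(self):
        a = cq.ConsequenceCall("v", "tA", cq.INTRONIC)
        b = cq.ConsequenceCall("v", "tB", cq.STOP_GAINED)
        assert cq.rank_calls([a, b])[0] is b

    def test_single_call_unchanged(self):
        a = cq.ConsequenceCall("v", "tA", cq.INTRONIC)
        assert cq.rank_calls([a]) == [a]

    def test_ties_break_by_transcript_id(self):
        a = cq.ConsequenceCall("v", "tB", cq.INTRONIC)
        b = cq.ConsequenceCall("v", "tA", cq.INTRONIC)
        assert [c.transcript_id for c in cq.rank_calls([a, b])] == ["tA", "tB"]

    def test_unknown_label_rejected(self):
        with pytest.raises(Exception):
            cq.ConsequenceCall("v", "t", "made-up label")


class TestFrameConservation:
    @pytest.mark.parametrize("length", [3, 6, 9])
    def test_in_frame_deletions_never_frameshift(self, t_plus, genome, length):
        start = 8_960
        ref = genome.fetch("chr1", start, start + length - 1)
        v = VariantRecord("chr1", start, start + length - 1, ref, [""], id="d")
        labels = {c.consequence_type for c in cq.classify(v, t_plus, genome)}
        assert cq.FRAMESHIFT not in labels and cq.FRAMESHIFT_SPLICE not in labels
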