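"""NQS caller: threshold boundaries, oracle equivalence, planted-SNP recovery."""

import random

import pytest

from varkit.caller import (
    CallerConfig,
    call_snps,
    coverage_ranges,
    nqs_pass,
    sara_genotype,
)
from varkit.fixtures import FixtureSpec, PlantedSnp, make_genome_and_annotation, make_reads
from varkit.genome_model import ReferenceGenome
from varkit.io_formats import MATE_IMPROPER, MATE_PROPER, AlignedRead, VariantRecord

from oracles import bf_call_snps, bf_coverage

CFG = CallerConfig()

REF = ("ACGTTGCAGT" * 60)  # 600 bp toy reference
GENOME = ReferenceGenome({"c": REF})
POS = 150  # variant site for most scenarios


def mk_read(
    rid,
    start=101,
    length=100,
    subs=(),  # (genomic_pos, base)
    quals=None,  # (genomic_pos, qual) overrides
    default_qual=30,
    mate=MATE_PROPER,
    individual="ind",
):
    bases = list(GENOME.fetch("c", start, start + length - 1))
    q = [default_qual] * length
    for pos, b in subs:
        bases[pos - start] = b
    for pos, value in quals or ():
        q[pos - start] = value
    return AlignedRead(
        read_id=rid,
        seq_name="c",
        start=start,
        read_seq="".join(bases),
        quals=q,
        cigar=[("M", length)],
        mate_status=mate,
        individual=individual,
    )


def alt_base(pos=POS):
    ref = GENOME.base("c", pos)
    return "A" if ref != "A" else "G"


def _site_calls(reads, cfg=CFG, coverage=1.0):
    calls = call_snps(reads, GENOME, cfg, genome_coverage=coverage)
    assert {(c.seq_name, c.pos, c.individual): c.counts for c in calls} == bf_call_snps(
        reads, GENOME, cfg, coverage
    )
    return [c for c in calls if c.pos == POS]


class TestNqsBoundaries:
    """The exact threshold edges of the neighbourhood quality standard."""

    def _reads(self, n_alt=2, n_ref=2, **alt_kwargs):
        alt = alt_base()
        reads = [
            mk_read(f"a{i}", subs=[(POS, alt)], **alt_kwargs) for i in range(n_alt)
        ]
        reads += [mk_read(f"r{i}") for i in range(n_ref)]
        return reads

    @pytest.mark.parametrize("vq,called", [(22, False), (23, True)])
    def test_variant_quality_threshold(self, vq, called):
        reads = self._reads(quals=[(POS, vq)])
        assert bool(_site_calls(reads)) == called

    @pytest.mark.parametrize("fq,called", [(15, False), (16, True)])
    def test_flank_quality_threshold(self, fq, called):
        reads = self._reads(quals=[(POS - 3, fq)])
        assert bool(_site_calls(reads)) == called

    @pytest.mark.parametrize("n_mm,called", [(1, True), (2, False)])
    def test_flank_mismatch_window(self, n_mm, called):
        # mismatches inside +-10 but outside the exact +-5 flank
        mm_pos = [POS + 7, POS + 9][:n_mm]
        subs = [(POS, alt_base())] + [(p, alt_base(p)) for p in mm_pos]
        alt = alt_base()
        reads = [mk_read(f"a{i}", subs=subs) for i in range(2)]
        reads += [mk_read(f"r{i}") for i in range(2)]
        site = [c for c in call_snps(reads, GENOME, CFG) if c.pos == POS]
        assert bool(site) == called
        assert (("c", POS, "ind") in bf_call_snps(reads, GENOME, CFG)) == called

    @pytest.mark.parametrize("n_mm,called", [(30, True), (31, False)])
    def test_read_mismatch_cap(self, n_mm, called):
        # pile the extra mismatches well away from the variant base
        alt = alt_base()
        far = [(401 + 2 * k, alt_base(401 + 2 * k)) for k in range(n_mm - 1)]
        reads = [
            mk_read(f"a{i}", start=101, length=500, subs=[(POS, alt)] + far)
            for i in range(2)
        ]
        reads += [mk_read(f"r{i}") for i in range(2)]
        assert bool(_site_calls(reads)) == called

    @pytest.mark.parametrize("depth,called", [(100, True), (101, False)])
    def test_site_depth_cap(self, depth, called):
        alt = alt_base()
        reads = [
            mk_read(f"x{i}", subs=[(POS, alt)] if i % 2 == 0 else [])
            for i in range(depth)
        ]
        assert bool(_site_calls(reads)) == called

    @pytest.mark.parametrize("n_alt,called", [(1, False), (2, True)])
    def test_minor_allele_support_at_depth_four(self, n_alt, called):
        reads = self._reads(n_alt=n_alt, n_ref=4 - n_alt)
        assert bool(_site_calls(reads)) == called

    def test_minor_rule_not_applied_below_depth_four(self):
        # coverage of 3 is not "greater than 3": a single minor read suffices
        reads = self._reads(n_alt=1, n_ref=2)
        (call,) = _site_calls(reads)
        assert call.counts == {GENOME.base("c", POS): 2, alt_base(): 1}

    def test_insufficient_flank_near_read_end_fails(self):
        read = mk_read("e", start=POS - 2, length=50, subs=[(POS, alt_base())])
        assert nqs_pass(read, 2, CFG, GENOME) is False


class TestCallerPipeline:
    def test_improperly_paired_reads_are_dropped(self):
        alt = alt_base()
        reads = [
            mk_read(f"a{i}", subs=[(POS, alt)], mate=MATE_IMPROPER) for i in range(2)
        ] + [mk_read(f"r{i}") for i in range(3)]
        assert _site_calls(reads) == []

    def test_three_alleles_for_one_individual_discard_the_site(self):
        ref = GENOME.base("c", POS)
        others = [b for b in "ACGT" if b != ref][:2]
        reads = [mk_read(f"m{i}", subs=[(POS, b)]) for i, b in enumerate(others)]
        reads += [mk_read("r0"), mk_read("r1")]
        assert _site_calls(reads) == []

    def test_low_coverage_scales_read_and_depth_filters(self):
        alt = alt_base()
        # 20 mismatches pass the full cap (30) but not the scaled cap (15)
        far = [(401 + 2 * k, alt_base(401 + 2 * k)) for k in range(19)]
        reads = [
            mk_read(f"a{i}", start=101, length=500, subs=[(POS, alt)] + far)
            for i in range(2)
        ] + [mk_read(f"r{i}") for i in range(2)]
        assert _site_calls(reads, coverage=1.0)
        assert _site_calls(reads, coverage=0.05) == []

    def test_raising_variant_quality_never_adds_calls(self):
        spec = FixtureSpec(seed=3, read_region=(7_500, 10_500), read_depth=6.0)
        genome, _, _ = make_genome_and_annotation(spec)
        reads, _ = make_reads(spec, genome)
        seen = None
        for phred in (10, 20, 23, 30, 36):
            cfg = CallerConfig(min_variant_phred=phred)
            keys = {(c.pos, c.individual) for c in call_snps(reads, genome, cfg)}
            if seen is not None:
                assert keys <= seen
            seen = keys

    def test_output_independent_of_read_order(self):
        spec = FixtureSpec(seed=4, read_region=(7_500, 10_500), read_depth=6.0)
        genome, _, _ = make_genome_and_annotation(spec)
        reads, _ = make_reads(spec, genome)
        shuffled = reads[:]
        random.Random(0).shuffle(shuffled)
        assert call_snps(reads, genome) == call_snps(shuffled, genome)

    def test_matches_literal_rule_oracle_on_small_fixture(self):
        spec = FixtureSpec(seed=5, read_region=(7_500, 10_500), read_depth=6.0)
        genome, _, _ = make_genome_and_annotation(spec)
        reads, _ = make_reads(spec, genome)
        assert len(reads) <= 50
        got = {(c.seq_name, c.pos, c.individual): c.counts for c in call_snps(reads, genome)}
        assert got == bf_call_snps(reads, genome, CFG)

    def test_planted_snps_recovered_without_false_positives(self, spec, genome, reads_and_truth):
        reads, truth = reads_and_truth
        calls = call_snps(reads, genome)
        called = {c.pos: c for c in calls}
        for t in truth:
            assert t["pos"] in called
            assert called[t["pos"]].alt_alleles == [t["alt"]]
        # error-free columns: no calls beyond planted sites and injected errors
        planted = {t["pos"] for t in truth}
        for pos in set(called) - planted:
            raise AssertionError(f"spurious call at {pos}")

    def test_forced_low_quality_planted_snp_is_not_called(self):
        spec = FixtureSpec(
            seed=6,
            planted_snps=[PlantedSnp(8_950), PlantedSnp(9_400, qual=22)],
        )
        genome, _, _ = make_genome_and_annotation(spec)
        reads, truth = make_reads(spec, genome)
        positions = {c.pos for c in call_snps(reads, genome)}
        assert 8_950 in positions and 9_400 not in positions
        assert [t["expected_called"] for t in truth] == [True, False]


class TestSara:
    def _known(self, pos=POS):
        ref = GENOME.base("c", pos)
        return [VariantRecord("c", pos, pos, ref, [alt_base(pos)], id="rs1")]

    def test_all_reference_reads_yield_sara(self):
        reads = [mk_read(f"r{i}") for i in range(4)]
        (call,) = sara_genotype(reads, self._known(), GENOME)
        assert call.sara and call.counts == {GENOME.base("c", POS): 4}

    def test_no_passing_reads_no_record(self):
        reads = [mk_read("r0", start=350, length=100)]  # does not cover POS
        assert sara_genotype(reads, self._known(), GENOME) == []

    def test_any_passing_alternative_blocks_sara(self):
        reads = [mk_read(f"r{i}") for i in range(3)]
        reads.append(mk_read("a0", subs=[(POS, alt_base())]))
        assert sara_genotype(reads, self._known(), GENOME) == []


class TestCoverage:
    def test_matches_interval_sweep_oracle_on_fixture(self, reads_and_truth):
        reads, _ = reads_and_truth
        assert coverage_ranges(reads) == bf_coverage(reads)

    def test_per_individual_filtering(self):
        reads = [
            mk_read("r0", start=101, individual="x"),
            mk_read("r1", start=151, individual="y"),
        ]
        assert coverage_ranges(reads, individual="x") == [("c", 101, 200, "1")]
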