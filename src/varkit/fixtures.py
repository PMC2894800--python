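"""Deterministic synthetic-data generator.

Everything the toolkit consumes — reference sequence, gene annotation,
regulatory features, quality-scored read alignments with planted
heterozygous SNPs, and population genotype panels with known two-locus
haplotype frequencies — is generated reproducibly from a single seed, with
per-output sub-streams so adding one output never shifts another. Truth
files accompany the reads and genotypes so downstream results can be scored
without reference to generation internals.

The fixture gene models are hand-placed rather than random: codons are
pinned at and away from splice junctions so that a single-base sweep over
the main coding transcript reaches every substitution consequence class
(stop gained/lost, synonymous, non-synonymous, each with and without the
splice-site modifier, both UTRs, intronic and splice classes, upstream,
downstream, intergenic). The reference CDS deliberately contains an
internal in-frame stop codon next to a splice junction; it exists only so
the "stop lost at a splice site" class is reachable and is labelled
synthetic here for that reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_model import ReferenceGenome, RegulatoryFeature, TranscriptModel
from .io_formats import (
    MATE_PROPER,
    AlignedRead,
    write_fasta,
    write_reads_tsv,
    write_sam,
)
from .popgen_ld import GenotypeMatrix, VariantSite

_BASES = "ACGT"

# sub-stream labels so each output has an independent, stable RNG
_STREAM = {"genome": 0, "reads": 1, "genotypes": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM[stream]]))


@dataclass
class PlantedSnp:
    """A heterozygous SNP to inject into the synthetic reads."""

    pos: int
    alt: str | None = None  # None: chosen as the next base after the reference
    qual: int | None = None  # force the variant-base quality (None: clean, 35)
    note: str = ""


@dataclass
class LdBlock:
    """Two genotyped SNPs drawn from fixed two-locus haplotype frequencies."""

    pos1: int
    pos2: int
    # (p_AB, p_Ab, p_aB, p_ab); A/B are the reference alleles
    hap_freqs: tuple[float, float, float, float]

    def __post_init__(self):
        if abs(sum(self.hap_freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")


def _default_planted() -> list[PlantedSnp]:
    return [
        PlantedSnp(7800, note="upstream"),
        PlantedSnp(8150, note="5' UTR"),
        PlantedSnp(8950, note="CDS"),
        PlantedSnp(9400, note="intronic"),
        PlantedSnp(10700, note="3' UTR"),
    ]


def _default_blocks() -> list[LdBlock]:
    return [
        LdBlock(21000, 22000, (0.5, 0.0, 0.0, 0.5)),  # complete LD
        LdBlock(23000, 24000, (0.25, 0.25, 0.25, 0.25)),  # equilibrium
        LdBlock(26000, 27000, (0.4, 0.1, 0.1, 0.4)),  # intermediate LD
    ]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic bundle.

    Read defaults emulate capillary (Sanger-style) resequencing of a single
    diploid individual: ~500 bp reads at ~8x depth with high base qualities,
    a low per-base error rate, and properly paired mates.
    """

    seed: int = 0
    seq_name: str = "chr1"
    genome_length: int = 30_000
    read_length: int = 500
    read_depth: float = 8.0
    read_region: tuple[int, int] = (7_200, 11_300)
    base_qual_mean: float = 34.0
    base_qual_sd: float = 4.0
    base_qual_floor: int = 20
    error_rate: float = 0.001
    error_qual: tuple[int, int] = (5, 15)
    individual: str = "ind1"
    planted_snps: list[PlantedSnp] = field(default_factory=_default_planted)
    n_samples: int = 60
    missing_rate: float = 0.01
    ld_blocks: list[LdBlock] = field(default_factory=_default_blocks)
    population_id: str = "POP1"


# ---------------------------------------------------------------------------
# genome + annotation

# main coding transcript (+ strand): 4 exons, CDS starts mid-exon 2 and ends
# mid-exon 3, so both UTRs have splice-adjacent exon bases
_TPLUS_EXONS = [(8_001, 8_200), (8_801, 9_100), (9_601, 10_000), (10_501, 10_900)]
_TPLUS_CDS = (8_901, 9_901)

# minus-strand coding transcript, used for strand round-trip checks
_TMINUS_EXONS = [(18_001, 18_600), (19_201, 19_800)]
_TMINUS_CDS = (18_102, 19_700)

# non-coding miRNA transcript with a mature sub-interval
_TNC_EXON = (24_001, 24_100)
_TNC_MATURE = (24_021, 24_042)

_REGULATORY = (26_000, 26_500)

# codons pinned onto the forward strand so the SNV sweep reaches every class:
#   8976 TGG  mid-CDS, one substitution from a stop      -> Stop gained
#   9000 GGA  mid-CDS, third position fourfold           -> Synonymous coding
#   9096 CTG  third base 3 bp from the junction          -> Splice site, synonymous
#   9099 TG|G codon split across intron 2                -> Stop gained, splice site
#   9602 TGA  reference stop 2 bp into exon 3 (synthetic) -> Stop lost, splice site
#   9899 TAA  terminal stop, far from junctions          -> Stop lost
_PINNED = {
    8_976: "TGG",
    9_000: "GGA",
    9_096: "CTG",
    9_099: "TG",
    9_601: "G",
    9_602: "TGA",
    9_899: "TAA",
}


def fixture_transcripts(seq_name: str = "chr1") -> list[TranscriptModel]:
    return [
        TranscriptModel(
            id="t_plus",
            gene_id="g_plus",
            seq_name=seq_name,
            strand=+1,
            exons=list(_TPLUS_EXONS),
            cds_start=_TPLUS_CDS[0],
            cds_end=_TPLUS_CDS[1],
            biotype="protein_coding",
        ),
        TranscriptModel(
            id="t_minus",
            gene_id="g_minus",
            seq_name=seq_name,
            strand=-1,
            exons=list(_TMINUS_EXONS),
            cds_start=_TMINUS_CDS[0],
            cds_end=_TMINUS_CDS[1],
            biotype="protein_coding",
        ),
        TranscriptModel(
            id="t_mir",
            gene_id="g_mir",
            seq_name=seq_name,
            strand=+1,
            exons=[_TNC_EXON],
            biotype="miRNA",
            mature_mirna=[_TNC_MATURE],
        ),
    ]


def make_genome_and_annotation(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> tuple[ReferenceGenome, list[TranscriptModel], list[RegulatoryFeature]]:
    """Random reference with the fixed gene models pinned onto it.

    When ``out_dir`` is given, writes genome.fa, annotation.gtf and
    regulatory.bed (byte-identical for a given spec).
    """
    rng = _rng(spec.seed, "genome")
    seq = list(rng.choice(list(_BASES), size=spec.genome_length))
    for start, bases in _PINNED.items():
        seq[start - 1 : start - 1 + len(bases)] = list(bases)
    genome = ReferenceGenome({spec.seq_name: "".join(seq)})
    transcripts = fixture_transcripts(spec.seq_name)
    regs = [RegulatoryFeature(spec.seq_name, *_REGULATORY, linked_gene="g_plus")]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out_dir / "genome.fa")
        _write_gtf(transcripts, out_dir / "annotation.gtf")
        with open(out_dir / "regulatory.bed", "w") as fh:
            for r in regs:
                gene = r.linked_gene or "."
                fh.write(f"{r.seq_name}\t{r.start - 1}\t{r.end}\t{gene}\n")
    return genome, transcripts, regs


def _write_gtf(transcripts: list[TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            strand = "+" if t.strand == +1 else "-"
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.id}"; '
                f'transcript_biotype "{t.biotype}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.seq_name}\tvarkit\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )
            if t.is_coding:
                for s, e in t.exons:
                    cs, ce = max(s, t.cds_start), min(e, t.cds_end)
                    if cs <= ce:
                        fh.write(
                            f"{t.seq_name}\tvarkit\tCDS\t{cs}\t{ce}\t.\t{strand}\t.\t{attrs}\n"
                        )
            for s, e in t.mature_mirna:
                fh.write(
                    f"{t.seq_name}\tvarkit\tmature_miRNA\t{s}\t{e}\t.\t{strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# reads with planted heterozygous SNPs


def _next_base(base: str) -> str:
    return _BASES[(_BASES.index(base) + 1) % 4]


def make_reads(
    spec: FixtureSpec,
    genome: ReferenceGenome,
    out_dir: str | Path | None = None,
) -> tuple[list[AlignedRead], list[dict]]:
    """Tile the read region with quality-scored reads carrying planted SNPs.

    Reads are evenly spaced with small jitter so every planted site has near
    the target depth. Alternate overlapping reads carry the alternative
    allele (~50%, a heterozygote). The variant base gets a clean quality of
    35 unless the planted SNP forces one, and sequencing errors (low-quality
    wrong bases) are kept out of a +-10 bp guard zone around planted sites.

    Returns the reads and a truth table (one dict per planted SNP with pos,
    ref, alt, forced qual and whether the caller is expected to report it).
    """
    rng = _rng(spec.seed, "reads")
    lo, hi = spec.read_region
    n_reads = max(2, int(round(spec.read_depth * (hi - lo) / spec.read_length)))
    last_start = hi - spec.read_length
    starts = np.linspace(lo, last_start, n_reads)
    starts = np.clip(
        np.round(starts + rng.integers(-20, 21, size=n_reads)), lo, last_start
    ).astype(int)
    starts.sort()

    planted = []
    for p in spec.planted_snps:
        ref = genome.base(spec.seq_name, p.pos)
        alt = p.alt or _next_base(ref)
        planted.append({"pos": p.pos, "ref": ref, "alt": alt, "qual": p.qual})
    guard = {
        q for p in planted for q in range(p["pos"] - 10, p["pos"] + 11)
    }
    toggle = {p["pos"]: False for p in planted}

    reads: list[AlignedRead] = []
    for k, start in enumerate(starts):
        end = start + spec.read_length - 1
        bases = list(genome.fetch(spec.seq_name, start, end))
        quals = np.maximum(
            np.round(
                rng.normal(spec.base_qual_mean, spec.base_qual_sd, spec.read_length)
            ).astype(int),
            spec.base_qual_floor,
        )
        # sequencing errors, kept away from planted sites
        n_err = rng.binomial(spec.read_length, spec.error_rate)
        for off in rng.integers(0, spec.read_length, size=n_err):
            if start + off in guard:
                continue
            bases[off] = _next_base(bases[off])
            quals[off] = rng.integers(spec.error_qual[0], spec.error_qual[1] + 1)
        # planted heterozygous SNPs: alternate allele on every other read
        for p in planted:
            if not start <= p["pos"] <= end:
                continue
            off = p["pos"] - start
            toggle[p["pos"]] = not toggle[p["pos"]]
            if toggle[p["pos"]]:
                bases[off] = p["alt"]
            quals[off] = p["qual"] if p["qual"] is not None else 35
        reads.append(
            AlignedRead(
                read_id=f"read{k:04d}",
                seq_name=spec.seq_name,
                start=int(start),
                read_seq="".join(bases),
                quals=[int(q) for q in quals],
                cigar=[("M", spec.read_length)],
                mate_status=MATE_PROPER,
                individual=spec.individual,
            )
        )

    truth = [
        {
            "pos": p["pos"],
            "ref": p["ref"],
            "alt": p["alt"],
            "qual": p["qual"],
            "expected_called": p["qual"] is None or p["qual"] >= 23,
        }
        for p in planted
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_sam(reads, genome, out_dir / "reads.sam")
        write_reads_tsv(reads, out_dir / "reads.tsv")
        with open(out_dir / "truth_snps.tsv", "w") as fh:
            fh.write("pos\tref\talt\tqual\texpected_called\n")
            for t in truth:
                fh.write(
                    f"{t['pos']}\t{t['ref']}\t{t['alt']}\t"
                    f"{t['qual'] if t['qual'] is not None else '.'}\t"
                    f"{int(t['expected_called'])}\n"
                )
    return reads, truth


# ---------------------------------------------------------------------------
# population genotypes with known haplotype frequencies


def make_genotypes(
    spec: FixtureSpec,
    genome: ReferenceGenome,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Unphased diploid genotypes drawn blockwise from fixed haplotype
    frequencies; the truth table records each block's target frequencies."""
    rng = _rng(spec.seed, "genotypes")
    samples = [f"s{i:03d}" for i in range(spec.n_samples)]
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    truth: list[dict] = []
    for b, block in enumerate(spec.ld_blocks):
        ids = (f"snp{b}a", f"snp{b}b")
        # two haplotypes per sample, categorical over (AB, Ab, aB, ab)
        haps = rng.choice(4, size=(spec.n_samples, 2), p=list(block.hap_freqs))
        alt1 = ((haps == 2) | (haps == 3)).sum(axis=1)  # 'a' at locus 1
        alt2 = ((haps == 1) | (haps == 3)).sum(axis=1)  # 'b' at locus 2
        for vid, pos, col in ((ids[0], block.pos1, alt1), (ids[1], block.pos2, alt2)):
            ref = genome.base(spec.seq_name, pos)
            sites.append(VariantSite(vid, spec.seq_name, pos, ref, _next_base(ref)))
            col = col.astype(np.int8)
            if spec.missing_rate > 0:
                miss = rng.random(spec.n_samples) < spec.missing_rate
                col = np.where(miss, np.int8(-1), col)
            columns.append(col)
        truth.append(
            {"id1": ids[0], "id2": ids[1], "p": list(block.hap_freqs)}
        )
    geno = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((spec.n_samples, 0), dtype=np.int8)
    )
    g = GenotypeMatrix(spec.population_id, samples, sites, geno)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_genotype_vcf(g, out_dir / "genotypes.vcf")
        with open(out_dir / "truth_ld.json", "w") as fh:
            json.dump({"n_samples": spec.n_samples, "blocks": truth}, fh, indent=1)
    return g, truth


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_genotype_vcf(g: GenotypeMatrix, path: Path) -> None:
    order = sorted(range(len(g.variants)), key=lambda k: (g.variants[k].seq_name, g.variants[k].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for seq in sorted({v.seq_name for v in g.variants}):
            fh.write(f"##contig=<ID={seq}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for k in order:
            v = g.variants[k]
            gts = "\t".join(_GT_STRING[int(x)] for x in g.genotypes[:, k])
            fh.write(
                f"{v.seq_name}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# whole bundle


def simulate_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate the full fixture bundle into a directory.

    Writes genome.fa, annotation.gtf, regulatory.bed, reads.sam, reads.tsv,
    truth_snps.tsv, genotypes.vcf and truth_ld.json; returns the in-memory
    objects for programmatic use.
    """
    out_dir = Path(out_dir)
    genome, transcripts, regs = make_genome_and_annotation(spec, out_dir)
    reads, snp_truth = make_reads(spec, genome, out_dir)
    geno, ld_truth = make_genotypes(spec, genome, out_dir)
    return {
        "genome": genome,
        "transcripts": transcripts,
        "regulatory": regs,
        "reads": reads,
        "snp_truth": snp_truth,
        "genotypes": geno,
        "ld_truth": ld_truth,
    }
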