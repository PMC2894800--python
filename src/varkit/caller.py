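"""Neighbourhood-quality-standard (NQS) SNP discovery from aligned reads.

The caller scans mismatch columns in read alignments against the reference
assembly and reports a SNP only when the evidence is locally clean: the
variant base must be high quality (PHRED >= 23 by default), the five bases
on each side must align exactly with quality > 15, and at most one mismatch
is tolerated within ten flanking bases. Reads with excessive mismatches or
improperly paired mates are removed first, very deep columns are skipped,
and a minor-allele support rule suppresses singleton artefacts at
well-covered sites. The same evidence rules back SARA ("same as reference
assembly") genotyping at known loci.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .errors import ContractError, CoordinateError
from .genome_model import ReferenceGenome
from .io_formats import (
    MATE_IMPROPER,
    AlignedRead,
    VariantRecord,
    DEPTH_MULTI,
    DEPTH_SINGLE,
)


@dataclass
class CallerConfig:
    """Thresholds of the NQS caller.

    Defaults are the standard operating point of the method: variant base
    quality >= 23; exact, >15-quality alignment over +-5 bases; at most one
    mismatch within +-10 bases; reads with more than 30 mismatches and sites
    deeper than 100 reads excluded; at coverage below ~0.1x the read- and
    depth-filters are scaled down by ``low_coverage_scale``; with more than
    3 passing reads the minor allele needs at least 2 supporting reads.
    """

    min_variant_phred: int = 23
    min_flank_phred: int = 15
    exact_flank_bp: int = 5
    mismatch_window_bp: int = 10
    max_flank_mismatches: int = 1
    max_read_mismatches: int = 30
    max_site_depth: int = 100
    low_coverage_threshold: float = 0.1
    low_coverage_scale: float = 0.5
    min_minor_reads: int = 2
    min_depth_for_minor_rule: int = 4
    max_alleles_per_individual: int = 2

    def __post_init__(self):
        for name in (
            "min_variant_phred",
            "min_flank_phred",
            "exact_flank_bp",
            "mismatch_window_bp",
            "max_flank_mismatches",
            "max_read_mismatches",
            "max_site_depth",
            "min_minor_reads",
            "min_depth_for_minor_rule",
            "max_alleles_per_individual",
        ):
            if getattr(self, name) < 1 and name != "max_flank_mismatches":
                raise ContractError(f"{name} must be positive")
        if self.exact_flank_bp > self.mismatch_window_bp:
            raise ContractError("exact_flank_bp must be <= mismatch_window_bp")

    def effective(self, genome_coverage: float) -> tuple[int, int]:
        """(max_read_mismatches, max_site_depth) after low-coverage scaling."""
        if genome_coverage < self.low_coverage_threshold:
            return (
                max(1, int(self.max_read_mismatches * self.low_coverage_scale)),
                max(1, int(self.max_site_depth * self.low_coverage_scale)),
            )
        return self.max_read_mismatches, self.max_site_depth


@dataclass
class SnpCall:
    """One per-individual call: a discovered SNP or a SARA genotype."""

    seq_name: str
    pos: int
    ref_allele: str
    alt_alleles: list[str]
    individual: str
    counts: dict[str, int] = field(default_factory=dict)
    sara: bool = False

    def __post_init__(self):
        if not self.sara and not self.alt_alleles:
            raise ContractError("non-SARA call must carry an alternative allele")


# ---------------------------------------------------------------------------
# per-read alignment profile

# per read offset: (kind, ref_pos, is_match); kind in {"M", "I", "S"}
_Profile = list[tuple[str, int | None, bool]]


def _profile(read: AlignedRead, genome: ReferenceGenome) -> _Profile:
    if read.seq_name not in genome.sequences:
        raise CoordinateError(
            f"read {read.read_id} aligned to unknown sequence {read.seq_name!r}"
        )
    prof: _Profile = []
    rpos = read.start
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                ref_base = genome.base(read.seq_name, rpos + i)
                prof.append(("M", rpos + i, read.read_seq[len(prof)] == ref_base))
            rpos += n
        elif op in "IS":
            prof.extend((op, None, False) for _ in range(n))
        elif op == "D":
            rpos += n
    return prof


def read_mismatches(read: AlignedRead, genome: ReferenceGenome) -> int:
    """Substitution mismatches of the whole read against the reference."""
    return sum(1 for kind, _, match in _profile(read, genome) if kind == "M" and not match)


def _is_window_mismatch(entry: tuple[str, int | None, bool]) -> bool:
    kind, _, match = entry
    return (kind == "M" and not match) or kind == "I"


def nqs_pass(
    read: AlignedRead,
    read_offset: int,
    cfg: CallerConfig,
    genome: ReferenceGenome,
    profile: _Profile | None = None,
) -> bool:
    """Neighbourhood quality standard for one read base.

    True iff the base at ``read_offset`` has PHRED >= min_variant_phred, every
    base within +-exact_flank_bp exists, aligns as an exact match and has
    PHRED > min_flank_phred, and at most max_flank_mismatches mismatches fall
    within +-mismatch_window_bp (variant base excluded; the window truncates
    at read ends). Insufficient flank near a read end fails, it is not an
    error.
    """
    prof = profile if profile is not None else _profile(read, genome)
    if not 0 <= read_offset < len(prof):
        raise ContractError(f"read offset {read_offset} outside read")
    if prof[read_offset][0] != "M":
        return False
    if read.quals[read_offset] < cfg.min_variant_phred:
        return False
    for d in range(1, cfg.exact_flank_bp + 1):
        for off in (read_offset - d, read_offset + d):
            if not 0 <= off < len(prof):
                return False  # insufficient flank
            kind, _, match = prof[off]
            if kind != "M" or not match:
                return False
            if read.quals[off] <= cfg.min_flank_phred:
                return False
    lo = max(0, read_offset - cfg.mismatch_window_bp)
    hi = min(len(prof) - 1, read_offset + cfg.mismatch_window_bp)
    mismatches = sum(
        1
        for off in range(lo, hi + 1)
        if off != read_offset and _is_window_mismatch(prof[off])
    )
    return mismatches <= cfg.max_flank_mismatches


# ---------------------------------------------------------------------------
# pileup machinery


def _surviving_reads(
    reads: list[AlignedRead],
    genome: ReferenceGenome,
    max_mm: int,
) -> list[tuple[AlignedRead, _Profile]]:
    out = []
    for read in reads:
        if read.mate_status == MATE_IMPROPER:
            continue
        prof = _profile(read, genome)
        mm = sum(1 for kind, _, match in prof if kind == "M" and not match)
        if mm > max_mm:
            continue
        out.append((read, prof))
    return out


def _column_index(
    survivors: list[tuple[AlignedRead, _Profile]],
) -> tuple[dict, dict]:
    """depth per (seq, pos) and per-column observations.

    Observations map (seq, pos) -> list of (read, profile, read_offset).
    Depth counts aligned (M) bases of surviving reads, before NQS filtering.
    """
    depth: dict[tuple[str, int], int] = Counter()
    obs: dict[tuple[str, int], list] = defaultdict(list)
    for read, prof in survivors:
        for off, (kind, rpos, _match) in enumerate(prof):
            if kind == "M":
                key = (read.seq_name, rpos)
                depth[key] += 1
                obs[key].append((read, prof, off))
    return depth, obs


def _passing_bases_by_individual(
    column: list, cfg: CallerConfig, genome: ReferenceGenome
) -> dict[str, list[str]]:
    by_ind: dict[str, list[str]] = defaultdict(list)
    for read, prof, off in column:
        if nqs_pass(read, off, cfg, genome, profile=prof):
            by_ind[read.individual].append(read.read_seq[off])
    return by_ind


def _passes_minor_rule(bases: list[str], cfg: CallerConfig) -> bool:
    if len(bases) >= cfg.min_depth_for_minor_rule:
        counts = Counter(bases)
        return min(counts.values()) >= cfg.min_minor_reads
    return True


def call_snps(
    reads: list[AlignedRead],
    genome: ReferenceGenome,
    cfg: CallerConfig | None = None,
    genome_coverage: float = 1.0,
) -> list[SnpCall]:
    """Discover SNPs from aligned reads, one call per (site, individual).

    Pipeline: drop high-mismatch and improperly paired reads; skip columns
    deeper than the site-depth cap; keep only NQS-passing base observations;
    discard sites where any individual shows more than two distinct alleles;
    apply the minor-allele support rule at well-covered sites.
    """
    cfg = cfg or CallerConfig()
    max_mm, max_depth = cfg.effective(genome_coverage)
    survivors = _surviving_reads(reads, genome, max_mm)
    depth, obs = _column_index(survivors)

    # candidate columns: at least one surviving read mismatches there
    candidates = sorted(
        key
        for key, column in obs.items()
        if any(not prof[off][2] for _read, prof, off in column)
    )
    calls: list[SnpCall] = []
    for key in candidates:
        if depth[key] > max_depth:
            continue
        seq, pos = key
        ref = genome.base(seq, pos)
        by_ind = _passing_bases_by_individual(obs[key], cfg, genome)
        if any(
            len(set(bases)) > cfg.max_alleles_per_individual
            for bases in by_ind.values()
        ):
            continue  # site discarded outright
        for ind in sorted(by_ind):
            bases = by_ind[ind]
            alts = sorted(set(bases) - {ref})
            if not alts:
                continue
            if not _passes_minor_rule(bases, cfg):
                continue
            calls.append(
                SnpCall(
                    seq_name=seq,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=alts,
                    individual=ind,
                    counts=dict(Counter(bases)),
                )
            )
    calls.sort(key=lambda c: (c.seq_name, c.pos, c.individual))
    return calls


def sara_genotype(
    reads: list[AlignedRead],
    known_variants: list[VariantRecord],
    genome: ReferenceGenome,
    cfg: CallerConfig | None = None,
    genome_coverage: float = 1.0,
) -> list[SnpCall]:
    """SARA genotyping: confirm reference homozygosity at known SNP loci.

    A SARA record is emitted for an individual at a known locus when every
    NQS-passing observation equals the reference allele under the same
    depth and support rules as discovery. Loci with any passing alternative
    observation are left to ``call_snps``.
    """
    cfg = cfg or CallerConfig()
    max_mm, max_depth = cfg.effective(genome_coverage)
    survivors = _surviving_reads(reads, genome, max_mm)
    depth, obs = _column_index(survivors)

    calls: list[SnpCall] = []
    for var in known_variants:
        if var.start != var.end or len(var.ref_allele) != 1:
            continue  # SARA applies to SNP loci
        key = (var.seq_name, var.start)
        ref = genome.base(var.seq_name, var.start)
        if key not in obs or depth[key] > max_depth:
            continue
        by_ind = _passing_bases_by_individual(obs[key], cfg, genome)
        for ind in sorted(by_ind):
            bases = by_ind[ind]
            if not bases or any(b != ref for b in bases):
                continue
            if not _passes_minor_rule(bases, cfg):
                continue
            calls.append(
                SnpCall(
                    seq_name=var.seq_name,
                    pos=var.start,
                    ref_allele=ref,
                    alt_alleles=[],
                    individual=ind,
                    counts={ref: len(bases)},
                    sara=True,
                )
            )
    calls.sort(key=lambda c: (c.seq_name, c.pos, c.individual))
    return calls


def coverage_ranges(
    reads: list[AlignedRead], individual: str | None = None
) -> list[tuple[str, int, int, str]]:
    """Maximal constant-depth-class intervals covered by the reads.

    Depth class is "1" for single-read coverage and "2+" for at least two
    reads; uncovered gaps separate ranges. Filtered to one individual when
    given.
    """
    events: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for read in reads:
        if individual is not None and read.individual != individual:
            continue
        events[read.seq_name][read.start] += 1
        events[read.seq_name][read.ref_end() + 1] -= 1
    out: list[tuple[str, int, int, str]] = []
    for seq in sorted(events):
        positions = sorted(events[seq])
        depth = 0
        run_start, run_class = None, None
        for p in positions:
            depth += events[seq][p]
            cls = None if depth == 0 else (DEPTH_SINGLE if depth == 1 else DEPTH_MULTI)
            if cls != run_class:
                if run_class is not None:
                    out.append((seq, run_start, p - 1, run_class))
                run_start, run_class = p, cls
        # the final event always returns depth to 0, closing the last run
    return out
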