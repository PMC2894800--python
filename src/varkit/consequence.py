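"""Transcript consequence annotation.

Every (variant, transcript) pair within 5 kb receives a consequence type
from a closed, severity-ordered vocabulary: coding effects (stop gained or
lost, frameshift, non-synonymous, synonymous, with splice-site modifiers
when the variant lies 1-3 bp into an exon), splice classes (the first or
last 2 bp of an intron are essential splice sites, 3-8 bp splice sites),
UTR and intronic classes, regulatory-region overlap, non-coding and mature
miRNA classes, and positional classes (upstream/downstream within 5 kb,
intergenic beyond). Indels whose length change is not a multiple of three
are frameshifts; indels spanning an exon/intron or CDS/UTR border are
complex indels. Calls are ranked by severity, most damaging first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError
from .genome_model import (
    ReferenceGenome,
    RegulatoryFeature,
    TranscriptModel,
    reverse_complement,
    translate_codon,
)
from .io_formats import VariantRecord
from .variant_store import MergedVariant

# consequence vocabulary in severity order (rank 1 = most severe)
STOP_GAINED = "Stop gained"
STOP_LOST = "Stop lost"
COMPLEX_INDEL = "complex InDel"
FRAMESHIFT = "Frameshift coding"
STOP_GAINED_FRAMESHIFT = "Stop gained, frameshift coding"
NON_SYNONYMOUS = "Non-synonymous coding"
STOP_GAINED_SPLICE = "Stop gained, splice site"
STOP_LOST_SPLICE = "Stop lost, splice site"
FRAMESHIFT_SPLICE = "Frameshift coding, splice site"
STOP_GAINED_FRAMESHIFT_SPLICE = "stop gained, Frameshift coding, splice site"
NON_SYNONYMOUS_SPLICE = "Non-Synonymous coding, splice site"
SYNONYMOUS = "Synonymous coding"
SPLICE_SYNONYMOUS = "Splice site, synonymous coding"
REGULATORY_REGION = "Regulatory region"
WITHIN_MATURE_MIRNA = "Within mature miRNA"
UTR_5 = "5' UTR"
SPLICE_UTR_5 = "Splice site, 5' UTR"
UTR_3 = "3' UTR"
SPLICE_UTR_3 = "Splice site, 3' UTR"
INTRONIC = "Intronic"
ESSENTIAL_SPLICE_SITE = "Essential splice site, intronic"
SPLICE_SITE_INTRONIC = "Splice site, intronic"
UPSTREAM = "Upstream"
DOWNSTREAM = "Downstream"
WITHIN_NON_CODING_GENE = "Within non-coding gene"
INTERGENIC = "Intergenic"

SEVERITY: tuple[str, ...] = (
    STOP_GAINED,
    STOP_LOST,
    COMPLEX_INDEL,
    FRAMESHIFT,
    STOP_GAINED_FRAMESHIFT,
    NON_SYNONYMOUS,
    STOP_GAINED_SPLICE,
    STOP_LOST_SPLICE,
    FRAMESHIFT_SPLICE,
    STOP_GAINED_FRAMESHIFT_SPLICE,
    NON_SYNONYMOUS_SPLICE,
    SYNONYMOUS,
    SPLICE_SYNONYMOUS,
    REGULATORY_REGION,
    WITHIN_MATURE_MIRNA,
    UTR_5,
    SPLICE_UTR_5,
    UTR_3,
    SPLICE_UTR_3,
    INTRONIC,
    ESSENTIAL_SPLICE_SITE,
    SPLICE_SITE_INTRONIC,
    UPSTREAM,
    DOWNSTREAM,
    WITHIN_NON_CODING_GENE,
    INTERGENIC,
)

_RANK = {label: i + 1 for i, label in enumerate(SEVERITY)}

#: scope distance for transcript association
TRANSCRIPT_FLANK_BP = 5000
#: essential splice region: first/last bases of an intron
ESSENTIAL_SPLICE_BP = 2
#: splice-site region extends this far into an intron
INTRON_SPLICE_BP = 8
#: splice-site modifier fires this far into an exon
EXON_SPLICE_BP = 3


@dataclass
class ConsequenceCall:
    """One consequence assignment for a (variant, transcript) pair."""

    variant_id: str
    transcript_id: str | None
    consequence_type: str
    allele: str | None = None
    cdna_pos: int | None = None
    cds_pos: int | None = None
    protein_pos: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    def __post_init__(self):
        if self.consequence_type not in _RANK:
            raise ContractError(
                f"unknown consequence type {self.consequence_type!r}"
            )

    @property
    def rank(self) -> int:
        return _RANK[self.consequence_type]


def rank_calls(calls: list[ConsequenceCall]) -> list[ConsequenceCall]:
    """Stable severity sort, most severe first; ties by transcript id."""
    return sorted(calls, key=lambda c: (c.rank, c.transcript_id or ""))


# ---------------------------------------------------------------------------
# scope


def _footprint(start: int, end: int) -> tuple[int, int]:
    """Genomic interval touched by the variant; an insertion (start=end+1)
    touches its two flanking bases."""
    return min(start, end), max(start, end)


def transcripts_in_scope(
    seq_name: str,
    start: int,
    end: int,
    transcripts: list[TranscriptModel],
    regulatory: list[RegulatoryFeature] = (),
) -> tuple[list[TranscriptModel], list[RegulatoryFeature]]:
    """Transcripts whose span +-5 kb contains the variant, and overlapping
    regulatory features. Both empty means the variant is intergenic."""
    lo, hi = _footprint(start, end)
    txs = [
        t
        for t in transcripts
        if t.seq_name == seq_name
        and lo <= t.span[1] + TRANSCRIPT_FLANK_BP
        and hi >= t.span[0] - TRANSCRIPT_FLANK_BP
    ]
    regs = [
        r
        for r in regulatory
        if r.seq_name == seq_name and lo <= r.end and hi >= r.start
    ]
    return txs, regs


# ---------------------------------------------------------------------------
# per-allele classification against one transcript


def _is_snv(start: int, end: int, ref: str, alt: str) -> bool:
    return start == end and len(ref) == 1 and len(alt) == 1


def _splice_modifier(t: TranscriptModel, positions: list[int]) -> bool:
    """True when any footprint base lies 1-3 bp into an exon from a splice
    junction."""
    for p in positions:
        d = t.exon_edge_offset(p)
        if d is not None and d <= EXON_SPLICE_BP:
            return True
    return False


def _intron_label(min_offset: int) -> str:
    if min_offset <= ESSENTIAL_SPLICE_BP:
        return ESSENTIAL_SPLICE_SITE
    if min_offset <= INTRON_SPLICE_BP:
        return SPLICE_SITE_INTRONIC
    return INTRONIC


def _classify_snv(
    variant_id: str,
    pos: int,
    ref: str,
    alt: str,
    t: TranscriptModel,
    genome: ReferenceGenome,
) -> ConsequenceCall:
    intr = t.intron_offset(pos)
    if intr is not None:
        return ConsequenceCall(variant_id, t.id, _intron_label(intr[1]), allele=alt)
    region = t.cds_region(pos)
    splice = _splice_modifier(t, [pos])
    cdna = t.genomic_to_cdna(pos)
    if region == "5utr":
        label = SPLICE_UTR_5 if splice else UTR_5
        return ConsequenceCall(variant_id, t.id, label, allele=alt, cdna_pos=cdna)
    if region == "3utr":
        label = SPLICE_UTR_3 if splice else UTR_3
        return ConsequenceCall(variant_id, t.id, label, allele=alt, cdna_pos=cdna)
    # CDS single-base substitution: translate the affected codon
    cds_pos, codon_idx, codon_off = t.genomic_to_cds(pos)
    ref_codon = t.codon_at(codon_idx, genome)
    alt_tx = alt if t.strand == +1 else reverse_complement(alt)
    alt_codon = ref_codon[:codon_off] + alt_tx + ref_codon[codon_off + 1 :]
    ref_aa = translate_codon(ref_codon)
    alt_aa = translate_codon(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        label = STOP_GAINED_SPLICE if splice else STOP_GAINED
    elif ref_aa == "*" and alt_aa != "*":
        label = STOP_LOST_SPLICE if splice else STOP_LOST
    elif ref_aa == alt_aa and "X" not in (ref_aa, alt_aa):
        label = SPLICE_SYNONYMOUS if splice else SYNONYMOUS
    else:
        # includes the unknown-residue (N-containing) case
        label = NON_SYNONYMOUS_SPLICE if splice else NON_SYNONYMOUS
    return ConsequenceCall(
        variant_id,
        t.id,
        label,
        allele=alt,
        cdna_pos=cdna,
        cds_pos=cds_pos,
        protein_pos=codon_idx,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def _classify_indel(
    variant_id: str,
    start: int,
    end: int,
    ref: str,
    alt: str,
    t: TranscriptModel,
    genome: ReferenceGenome,
) -> ConsequenceCall:
    lo, hi = _footprint(start, end)
    positions = [p for p in range(lo, hi + 1) if t.span[0] <= p <= t.span[1]]
    regions = {("intron" if t.intron_offset(p) else t.cds_region(p)) for p in positions}
    if len(regions) > 1:
        return ConsequenceCall(variant_id, t.id, COMPLEX_INDEL, allele=alt)
    region = regions.pop()
    if region == "intron":
        d = min(t.intron_offset(p)[1] for p in positions)
        return ConsequenceCall(variant_id, t.id, _intron_label(d), allele=alt)
    splice = _splice_modifier(t, positions)
    first_tx = positions[0] if t.strand == +1 else positions[-1]
    cdna = t.genomic_to_cdna(first_tx)
    if region == "5utr":
        label = SPLICE_UTR_5 if splice else UTR_5
        return ConsequenceCall(variant_id, t.id, label, allele=alt, cdna_pos=cdna)
    if region == "3utr":
        label = SPLICE_UTR_3 if splice else UTR_3
        return ConsequenceCall(variant_id, t.id, label, allele=alt, cdna_pos=cdna)
    # wholly inside the CDS
    net = len(alt) - len(ref)
    mapped = t.genomic_to_cds(first_tx)
    cds_pos, codon_idx = (mapped[0], mapped[1]) if mapped else (None, None)
    if net % 3 != 0:
        label = FRAMESHIFT_SPLICE if splice else FRAMESHIFT
    else:
        # in-frame change: closest coding-effect label available
        label = NON_SYNONYMOUS_SPLICE if splice else NON_SYNONYMOUS
    return ConsequenceCall(
        variant_id,
        t.id,
        label,
        allele=alt,
        cdna_pos=cdna,
        cds_pos=cds_pos,
        protein_pos=codon_idx,
    )


def _combine_multiallelic(
    calls: list[ConsequenceCall], variant_id: str, transcript_id: str
) -> list[ConsequenceCall]:
    """A multi-allelic variant with one stop-gain allele and one frameshift
    allele collapses those calls into the combined class."""
    gains = [c for c in calls if c.consequence_type in (STOP_GAINED, STOP_GAINED_SPLICE)]
    shifts = [c for c in calls if c.consequence_type in (FRAMESHIFT, FRAMESHIFT_SPLICE)]
    if not (gains and shifts):
        return calls
    splice = any(
        c.consequence_type in (STOP_GAINED_SPLICE, FRAMESHIFT_SPLICE)
        for c in gains + shifts
    )
    label = STOP_GAINED_FRAMESHIFT_SPLICE if splice else STOP_GAINED_FRAMESHIFT
    combined = ConsequenceCall(variant_id, transcript_id, label)
    rest = [c for c in calls if c not in gains and c not in shifts]
    return [combined] + rest


def classify(
    v: VariantRecord, t: TranscriptModel, genome: ReferenceGenome
) -> list[ConsequenceCall]:
    """Consequence calls for one variant against one in-scope transcript.

    Emits one call per alternative allele (SNV alleles are translated through
    the affected codon); a multi-allelic variant combining a stop gain with a
    frameshift yields the combined class instead of two calls.
    """
    lo, hi = _footprint(v.start, v.end)
    span_lo, span_hi = t.span
    if hi < span_lo or lo > span_hi:
        before = hi < span_lo
        upstream = before if t.strand == +1 else not before
        label = UPSTREAM if upstream else DOWNSTREAM
        return [ConsequenceCall(v.id, t.id, label)]
    if not t.is_coding:
        if t.mature_mirna and any(
            lo <= e and hi >= s for s, e in t.mature_mirna
        ):
            return [ConsequenceCall(v.id, t.id, WITHIN_MATURE_MIRNA)]
        return [ConsequenceCall(v.id, t.id, WITHIN_NON_CODING_GENE)]
    calls = []
    for alt in v.alt_alleles:
        if _is_snv(v.start, v.end, v.ref_allele, alt):
            calls.append(_classify_snv(v.id, v.start, v.ref_allele, alt, t, genome))
        else:
            calls.append(
                _classify_indel(v.id, v.start, v.end, v.ref_allele, alt, t, genome)
            )
    return _combine_multiallelic(calls, v.id, t.id)


# ---------------------------------------------------------------------------
# whole-set annotation


def annotate(
    variants: list[VariantRecord],
    transcripts: list[TranscriptModel],
    genome: ReferenceGenome,
    regulatory: list[RegulatoryFeature] = (),
) -> list[ConsequenceCall]:
    """Annotate every variant against every in-scope transcript.

    Variants with no transcript within 5 kb and no regulatory overlap are
    Intergenic; regulatory-feature overlap adds a Regulatory region call.
    Output is severity-ranked per variant.
    """
    out: list[ConsequenceCall] = []
    for v in variants:
        txs, regs = transcripts_in_scope(
            v.seq_name, v.start, v.end, transcripts, regulatory
        )
        calls: list[ConsequenceCall] = []
        for t in txs:
            calls.extend(classify(v, t, genome))
        for r in regs:
            calls.append(
                ConsequenceCall(v.id, r.linked_gene, REGULATORY_REGION)
            )
        if not calls:
            calls.append(ConsequenceCall(v.id, None, INTERGENIC))
        out.extend(rank_calls(calls))
    return out


def summary_consequence(calls: list[ConsequenceCall]) -> str:
    """Most severe consequence type among a variant's calls."""
    if not calls:
        raise ContractError("no calls to summarize")
    return min(calls, key=lambda c: c.rank).consequence_type


def annotate_merged(
    variants: list[MergedVariant],
    transcripts: list[TranscriptModel],
    genome: ReferenceGenome,
    regulatory: list[RegulatoryFeature] = (),
) -> list[ConsequenceCall]:
    """Annotate merged variants; failed variants (no displayed mapping) are
    skipped, multi-mapping variants are handled per mapping."""
    flat: list[VariantRecord] = []
    for mv in variants:
        for seq, start, end in mv.display_mappings:
            ref = mv.ref_allele if mv.ref_allele is not None else genome.fetch(seq, start, end)
            alts = [a for a in mv.alleles if a != ref]
            if not alts:
                continue
            flat.append(
                VariantRecord(
                    seq_name=seq,
                    start=start,
                    end=end,
                    ref_allele=ref,
                    alt_alleles=alts,
                    id=mv.primary_id,
                )
            )
    return annotate(flat, transcripts, genome, regulatory)
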