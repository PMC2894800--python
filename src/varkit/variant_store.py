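"""Variant merging, strand normalization, and failed-variant QC.

Variants reported by multiple sources at the same locus are collapsed into
one record whose primary identifier follows the preference rs > ss > other,
with the remaining identifiers kept as synonyms. All alleles are normalized
to the forward genome strand first. A post-processing classifier then flags
unreliable variants: mapping to the genome more than three times, not
mapping at all, carrying no allele that matches the reference, or carrying
more than three observed alleles. Failed variants keep their data but lose
their displayed mapping; a whitelist protects known-good variants from
being failed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .genome_model import ReferenceGenome, reverse_complement
from .io_formats import VariantRecord

# failure flags
MAPS_GT3 = "MAPS_GT3"
NO_MAPPING = "NO_MAPPING"
NO_REF_ALLELE_MATCH = "NO_REF_ALLELE_MATCH"
GT3_ALLELES = "GT3_ALLELES"
OTHER = "OTHER"  # reserved for future checks

FAILURE_TYPES = (MAPS_GT3, NO_MAPPING, NO_REF_ALLELE_MATCH, GT3_ALLELES, OTHER)

Mapping = tuple[str, int, int]


@dataclass
class MergedVariant:
    """A collapsed variant: one primary id, synonym ids, forward-strand
    alleles and zero or more genomic mappings."""

    primary_id: str
    synonyms: list[str] = field(default_factory=list)
    alleles: list[str] = field(default_factory=list)
    mappings: list[Mapping] = field(default_factory=list)
    ref_allele: str | None = None
    failed_types: set[str] = field(default_factory=set)
    whitelist: bool = False
    source: str = "unknown"

    @property
    def is_failed(self) -> bool:
        return bool(self.failed_types) and not self.whitelist

    @property
    def display_mappings(self) -> list[Mapping]:
        """Mappings shown downstream; failed variants display none."""
        return [] if self.is_failed else list(self.mappings)

    @property
    def alt_alleles(self) -> list[str]:
        return [a for a in self.alleles if a != self.ref_allele]


def normalize_strand(v: VariantRecord) -> VariantRecord:
    """Report all alleles on the forward (positive) strand; idempotent."""
    if v.strand == +1:
        return v
    return replace(
        v,
        ref_allele=reverse_complement(v.ref_allele),
        alt_alleles=[reverse_complement(a) for a in v.alt_alleles],
        strand=+1,
    )


_ID_CLASS = [re.compile(r"^rs\d+"), re.compile(r"^ss\d+")]


def _id_rank(identifier: str) -> int:
    for rank, pat in enumerate(_ID_CLASS):
        if pat.match(identifier):
            return rank
    return len(_ID_CLASS)


def _is_mapped(v: VariantRecord) -> bool:
    return bool(v.seq_name)


def merge_variants(variants: list[VariantRecord]) -> list[MergedVariant]:
    """Collapse co-located records into single variants.

    Records sharing exact coordinates (seq, start, end) collapse into one
    record; allele sets are unioned and the primary identifier is chosen by
    source preference (dbSNP rs > ss > other ids), the rest becoming
    synonyms. Identically named variants at several loci contribute multiple
    mappings to one record. Input must be strand-normalized; order of input
    does not affect the result.
    """
    for v in variants:
        if v.strand != +1:
            raise ValueError(f"variant {v.id} is not strand-normalized")

    # coordinate collapse
    by_locus: dict[Mapping | None, list[VariantRecord]] = {}
    for v in variants:
        key = (v.seq_name, v.start, v.end) if _is_mapped(v) else None
        by_locus.setdefault(key, []).append(v)

    locus_records: list[MergedVariant] = []
    for key, group in by_locus.items():
        ids: list[str] = []
        for v in sorted(group, key=lambda v: (_id_rank(v.id), v.id)):
            for identifier in [v.id, *v.synonyms]:
                if identifier not in ids and identifier != ".":
                    ids.append(identifier)
        alleles: list[str] = []
        ref = group[0].ref_allele if key is not None else None
        ordered = ([ref] if ref is not None else []) + [
            a for v in sorted(group, key=lambda v: (_id_rank(v.id), v.id))
            for a in v.alleles
        ]
        for a in ordered:
            if a not in alleles:
                alleles.append(a)
        locus_records.append(
            MergedVariant(
                primary_id=ids[0] if ids else ".",
                synonyms=ids[1:],
                alleles=alleles,
                mappings=[key] if key is not None else [],
                ref_allele=ref,
                source=";".join(sorted({v.source for v in group})),
            )
        )

    # same primary id at several loci -> one variant with several mappings
    by_id: dict[str, MergedVariant] = {}
    out: list[MergedVariant] = []
    for rec in sorted(
        locus_records, key=lambda r: (r.mappings[0] if r.mappings else ("", 0, 0))
    ):
        if rec.primary_id == ".":
            out.append(rec)
            continue
        seen = by_id.get(rec.primary_id)
        if seen is None:
            by_id[rec.primary_id] = rec
            out.append(rec)
        else:
            seen.mappings.extend(m for m in rec.mappings if m not in seen.mappings)
            seen.synonyms.extend(
                s for s in rec.synonyms if s not in seen.synonyms
            )
            seen.alleles.extend(a for a in rec.alleles if a not in seen.alleles)
    out.sort(key=lambda r: (r.mappings[0] if r.mappings else ("", 0, 0), r.primary_id))
    return out


def classify_failed(
    v: MergedVariant,
    genome: ReferenceGenome,
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> set[str]:
    """Failure flags for one merged variant.

    MAPS_GT3: more than three genomic mappings. NO_MAPPING: none.
    NO_REF_ALLELE_MATCH: no observed allele equals the reference base(s) at
    any mapping. GT3_ALLELES: more than three observed alleles. Whitelisted
    variants are never failed.
    """
    if v.whitelist or v.primary_id in whitelist or set(v.synonyms) & set(whitelist):
        v.whitelist = True
        return set()
    flags: set[str] = set()
    if len(v.mappings) > 3:
        flags.add(MAPS_GT3)
    if len(v.mappings) == 0:
        flags.add(NO_MAPPING)
    if v.mappings:
        matched = any(
            genome.fetch(seq, start, end) in v.alleles
            for seq, start, end in v.mappings
        )
        if not matched:
            flags.add(NO_REF_ALLELE_MATCH)
    if len(v.alleles) > 3:
        flags.add(GT3_ALLELES)
    return flags


def apply_qc(
    variants: list[MergedVariant],
    genome: ReferenceGenome,
    whitelist: frozenset[str] | set[str] = frozenset(),
) -> tuple[list[MergedVariant], list[MergedVariant]]:
    """Classify every variant; returns (passed, failed) partitions.

    Failure flags are recorded on each variant; failed variants lose their
    displayed mapping but are retained.
    """
    passed, failed = [], []
    for v in variants:
        v.failed_types = classify_failed(v, genome, whitelist)
        (failed if v.is_failed else passed).append(v)
    return passed, failed
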