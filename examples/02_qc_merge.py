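"""Merge co-located variant reports and flag unreliable variants.

Two sources report the same SNP under different identifiers; the merge
keeps the dbSNP rsID as primary and the other id as a synonym. The QC
classifier then fails variants that multimap, do not map, miss the
reference allele, or carry too many alleles — unless whitelisted.
"""

from varkit.genome_model import ReferenceGenome
from varkit.io_formats import VariantRecord
from varkit.variant_store import MergedVariant, apply_qc, merge_variants, normalize_strand

genome = ReferenceGenome({"1": "ACGT" * 50})

reported = [
    VariantRecord("1", 101, 101, "A", ["G"], id="rs123", source="dbSNP"),
    # the same locus reported on the minus strand by another source
    VariantRecord("1", 101, 101, "T", ["C"], id="ENSSNP7", source="resequencing", strand=-1),
]
merged = merge_variants([normalize_strand(v) for v in reported])
m = merged[0]
print(f"merged: {m.primary_id} (synonyms: {m.synonyms}) alleles {'/'.join(m.alleles)}")

suspects = merged + [
    MergedVariant("rs_multi", alleles=["A", "G"],
                  mappings=[("1", 10 + i, 10 + i) for i in range(4)]),
    MergedVariant("rs_noref", alleles=["G", "T"], mappings=[("1", 101, 101)]),
]
passed, failed = apply_qc(suspects, genome)
for v in failed:
    print(f"failed: {v.primary_id}  reasons={sorted(v.failed_types)}  "
          f"displayed mappings={v.display_mappings}")
print(f"{len(passed)} passed, {len(failed)} failed")
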