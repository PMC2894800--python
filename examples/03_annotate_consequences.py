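"""Assign transcript consequences to variants.

Classifies a handful of variants against the synthetic coding transcript:
a stop-gaining substitution, a splice-region base, a frameshifting
deletion, and an intergenic SNV. Calls are ranked by severity (rank 1 is
the most damaging class in the vocabulary).
"""

from varkit import consequence as cq
from varkit.fixtures import FixtureSpec, make_genome_and_annotation
from varkit.io_formats import VariantRecord

genome, transcripts, regs = make_genome_and_annotation(FixtureSpec(seed=1))

variants = [
    VariantRecord("chr1", 8978, 8978, "G", ["A"], id="stopper"),   # TGG -> TGA
    VariantRecord("chr1", 9102, 9102, genome.base("chr1", 9102), ["N"], id="donor"),
    VariantRecord("chr1", 8950, 8951, genome.fetch("chr1", 8950, 8951), [""], id="shift"),
    VariantRecord("chr1", 2000, 2000, genome.base("chr1", 2000),
                  ["A" if genome.base("chr1", 2000) != "A" else "C"], id="lonely"),
]
variants[1].alt_alleles = ["A" if genome.base("chr1", 9102) != "A" else "C"]

for call in cq.annotate(variants, transcripts, genome, regs):
    detail = ""
    if call.ref_codon:
        detail = f"  codon {call.ref_codon}>{call.alt_codon} ({call.ref_aa}>{call.alt_aa})"
    print(f"{call.variant_id:<8s} {call.transcript_id or '-':<8s} "
          f"rank {call.rank:>2d}  {call.consequence_type}{detail}")
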