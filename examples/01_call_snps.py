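"""Discover heterozygous SNPs from quality-scored read alignments.

Builds a small synthetic resequencing experiment (one diploid individual,
~8x coverage, five planted heterozygous SNPs) and runs the NQS caller.
Each call reports the alleles seen in NQS-passing reads and their counts:
roughly half the reads carry the alternative allele at a true het site.
"""

from varkit.caller import call_snps, coverage_ranges
from varkit.fixtures import FixtureSpec, make_genome_and_annotation, make_reads

spec = FixtureSpec(seed=1)
genome, transcripts, _ = make_genome_and_annotation(spec)
reads, truth = make_reads(spec, genome)

print(f"{len(reads)} reads of {spec.read_length} bp, one individual\n")
print("pos      ref  alt  read counts")
for call in call_snps(reads, genome):
    counts = ", ".join(f"{a}x{n}" for a, n in sorted(call.counts.items()))
    print(f"{call.pos:<8d} {call.ref_allele}    {','.join(call.alt_alleles)}    {counts}")

print("\nplanted truth:", [(t["pos"], t["alt"]) for t in truth])
ranges = coverage_ranges(reads)
multi = sum(e - s + 1 for _, s, e, c in ranges if c == "2+")
total = sum(e - s + 1 for _, s, e, _ in ranges)
print(f"coverage: {total} bp touched, {multi} bp at >=2 reads")
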