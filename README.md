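# varkit

A toolkit for the computational core of a genome-database variation
pipeline: discovering SNPs in an individual from quality-scored read
alignments against a reference assembly, merging and quality-controlling
variants from multiple sources, predicting each variant's consequence on
overlapping transcripts, and post-processing population genotypes into
linkage-disequilibrium (LD) tables and tag-SNP panels.

It is aimed at developers and bioinformaticians who need these classic
resequencing-era methods as a small, testable Python library with a thin
command-line layer, rather than as part of a database infrastructure.

## Methods at the core

**NQS SNP calling.** A substitution is accepted from an alignment column
only under the neighbourhood quality standard: the variant base has PHRED
quality ≥ 23, the five bases on each side align exactly to the assembly
with quality > 15, and at most one mismatch occurs within the ten flanking
bases. Reads with more than 30 mismatches or improperly paired mates are
removed, columns deeper than 100 reads are skipped (both caps are scaled
down below ~0.1× coverage), at most two alleles are allowed per individual
and site, and at sites covered by more than 3 passing reads the minor
allele needs at least 2 supporting reads. The same evidence rules drive
SARA ("same as reference assembly") genotyping at known loci, and read
coverage is exported as ranges of single-read vs ≥2-read depth.

**Variant QC.** Co-located reports collapse into one record (primary id
preference rs > ss > other, the rest kept as synonyms; alleles reported on
the forward strand). A variant fails QC if it maps more than three times,
does not map, has no allele matching the reference, or has more than three
observed alleles; failed variants keep their data but lose their displayed
mapping. A whitelist protects known-good variants.

**Consequence annotation.** Each (variant, transcript) pair within 5 kb
receives one label from a closed, severity-ranked vocabulary of 26
classes: coding effects (stop gained/lost, frameshift, non-synonymous,
synonymous — with a splice modifier when 1–3 bp into an exon), intronic
classes (essential splice site in the first/last 2 bp of an intron, splice
site at 3–8 bp), UTRs, upstream/downstream within 5 kb, regulatory-region
overlap, non-coding and mature-miRNA classes, and intergenic beyond 5 kb.
Indels with a length change not divisible by 3 are frameshifts; indels
spanning an exon/intron or CDS/UTR border are complex indels.

**LD and tag SNPs.** For two biallelic loci with unphased diploid
genotypes, haplotype frequencies are fitted by EM (only double
heterozygotes are phase-ambiguous), giving

    D  = p_AB − p_A·p_B
    D' = D / D_max,  D_max = min(p_A·p_b, p_a·p_B)  for D > 0
                     D_max = min(p_A·p_B, p_a·p_b)  for D < 0
    r² = D² / (p_A·p_a·p_B·p_b)

Pairwise LD is computed in 100 kb windows for populations of ≥ 40 samples;
pairs with r² < 0.05 are discarded. Tag-SNP selection walks variants in
MAF-descending order and removes any lower-MAF variant within the window
whose r² with a retained variant exceeds 0.99.

## Worked example

Everything is runnable without external data — a seeded generator builds
the reference, annotation, reads and genotype panels (see `examples/`):

```bash
python examples/01_call_snps.py
```

```
66 reads of 500 bp, one individual

pos      ref  alt  read counts
7800     T    A    Ax4, Tx5
8150     T    A    Ax5, Tx4
8950     A    C    Ax4, Cx5
9400     C    G    Cx4, Gx4
10700    T    A    Ax5, Tx4

planted truth: [(7800, 'A'), (8150, 'A'), (8950, 'C'), (9400, 'G'), (10700, 'A')]
coverage: 4093 bp touched, 4008 bp at >=2 reads
```

All five planted heterozygous SNPs are recovered, each supported by about
half of the overlapping reads (the other half carry the reference allele),
and no spurious site is called. Consequence annotation on the same bundle
(`examples/03_annotate_consequences.py`) prints, for instance:

```
stopper  t_plus   rank  1  Stop gained  codon TGG>TGA (W>*)
donor    t_plus   rank 21  Essential splice site, intronic
shift    t_plus   rank  4  Frameshift coding
lonely   -        rank 26  Intergenic
```

The same pipeline is available from the shell:

```bash
varkit --seed 1 simulate --out-dir fx
varkit call --sam fx/reads.sam --fasta fx/genome.fa --out-vcf calls.vcf
varkit annotate --vcf calls.vcf --gtf fx/annotation.gtf --fasta fx/genome.fa \
       --out-tsv consequences.tsv
varkit ld --vcf fx/genotypes.vcf --out-tsv ld.tsv
varkit tagsnp --vcf fx/genotypes.vcf --out tags.txt
```

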