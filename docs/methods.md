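# Methods

This note documents the models and procedures implemented in varkit, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Coordinate model

All coordinates are 1-based, fully closed intervals on the forward genome
strand. Insertions are located between two bases and written
`start = end + 1` with an empty reference allele; VCF's
shared-leading-base indel style is converted on read and restored on
write. Exons are stored in ascending genomic order; spliced (cDNA/CDS)
walks apply transcript orientation.

Splice-boundary offsets are strand-symmetric by construction: the distance
reported for an intronic base is the minimum of its distances to the two
intron ends (terminal base = 1), and the distance for an exonic base is
the minimum over the exon edges that abut an intron (transcript-terminal
edges are not splice boundaries). Donor and acceptor are deliberately not
distinguished — the classification vocabulary does not separate them, and
the symmetric minimum makes every boundary class independent of strand.
Exon-edge offsets beyond 8 bp are reported as absent; no class uses them.

## NQS SNP caller

A base observation supports a call only if

* variant-base PHRED ≥ `min_variant_phred` (default 23),
* every base within ± `exact_flank_bp` (5) exists in the read, aligns as
  an exact match, and has PHRED > `min_flank_phred` (15),
* at most `max_flank_mismatches` (1) mismatches occur within
  ± `mismatch_window_bp` (10), the variant base excluded.

The two flanking clauses are nested conditions (exact match within ±5, ≤1
mismatch within ±10), which makes both simultaneously satisfiable. The
±10 window truncates at read ends rather than disqualifying the base.
Mismatches are substitutions and inserted bases; deletion gaps do not
consume read bases and are not counted. Soft-clipped bases are unaligned
and fail the flank-match requirement when inside ±5.

Pipeline order: reads with more than `max_read_mismatches` (30)
substitution mismatches or improperly paired mates are dropped; columns
whose surviving-read depth exceeds `max_site_depth` (100) are skipped
(depth counts aligned reads before NQS filtering — the caps describe the
mapping environment, not the evidence); sites where any individual shows
more than `max_alleles_per_individual` (2) distinct passing alleles are
discarded outright; and when an individual's passing depth reaches
`min_depth_for_minor_rule` (4, i.e. coverage greater than 3) the minor
allele needs `min_minor_reads` (2) supporting reads. Below ~0.1× genome
coverage (`low_coverage_threshold`) the read- and depth-caps are scaled by
`low_coverage_scale` (0.5 — the method only states that the values are
reduced, so the factor is exposed as a parameter).

SARA genotyping applies identical evidence rules at known SNP loci and
emits a record only when every passing observation equals the reference
allele; a single passing alternative observation leaves the locus to the
discovery caller. Indel discovery is out of scope: indels enter through
VCF import only.

## Variant merging and QC

The collapse key is exact coordinate identity `(seq, start, end)`; allele
sets are unioned without a compatibility requirement. Primary-identifier
preference is rs > ss > any other id (lexicographic within a class, for
determinism); all non-primary ids become synonyms. Records sharing a
primary id at several loci contribute multiple mappings to one variant,
which is what makes the multimapping QC rule observable.

Failure flags: `MAPS_GT3` (> 3 mappings), `NO_MAPPING` (none),
`NO_REF_ALLELE_MATCH` (no observed allele equals the reference bases at
any mapping; for insertions the empty allele matches the empty reference
span), `GT3_ALLELES` (> 3 observed alleles). An `OTHER` flag is reserved
for future checks. Flags are independent and may co-occur. Whitelisted
ids are never failed. Failed variants keep their data but expose no
displayed mapping, and are excluded from consequence annotation and LD.

## Consequence engine

Severity is the fixed order of the 26-class vocabulary (rank 1 = stop
gained); `rank_calls` sorts stably with transcript-id tie-breaks, and a
variant's summary consequence is its minimum rank. Decision order per
(variant, transcript, allele):

1. outside the transcript span → upstream/downstream by side in
   transcript orientation (scope is span ± 5000 bp; farther → intergenic);
2. non-coding transcript → mature-miRNA interval overlap or
   within-non-coding-gene, regardless of exon/intron position;
3. intronic SNV → essential splice (offset ≤ 2), splice site (3–8),
   else intronic;
4. exonic SNV → 5'/3' UTR or CDS; a splice modifier attaches when the
   exon-edge offset is 1–3;
5. CDS SNV → the reference and alternative codons are translated in
   transcript orientation (split codons across junctions included) and
   compared: stop gained / stop lost / synonymous / non-synonymous;
6. indels: footprint spanning an exon/intron or CDS/UTR border → complex
   indel; wholly-CDS length change ≢ 0 (mod 3) → frameshift; in-frame
   wholly-CDS indels are reported as non-synonymous coding (the
   vocabulary has no dedicated in-frame-indel class, and this is the
   closest coding-effect label); an insertion's footprint is its two
   flanking bases, so insertions exactly at a border are complex;
7. a multi-allelic variant combining a stop-gain allele with a
   frameshift allele collapses to the combined class (splice-flavoured
   if either contributing call was).

Per-allele calls are emitted otherwise; multi-allelic variants therefore
produce one call per alternative allele. Codons containing N translate to
the unknown residue X rather than erroring; comparisons involving X are
reported as non-synonymous since synonymy cannot be established. Start
codon loss has no dedicated class and surfaces as non-synonymous coding.
Regulatory-region calls require an explicit BED input; without one the
class is unreachable. The 1–3 bp exon rule counts only intron-adjacent
edges, so single-exon transcripts never receive splice modifiers.

## LD estimation

Genotypes are ALT-allele counts (0/1/2, −1 missing); each pair uses
pairwise-complete samples only (`n_informative`). Because the allele
counts at each locus are directly observed, the two-locus likelihood has
a single free parameter and EM iterates only the coupling/repulsion split
of double heterozygotes:

* E-step: each AaBb individual contributes AB+ab with probability
  p_AB·p_ab / (p_AB·p_ab + p_Ab·p_aB), else Ab+aB;
* M-step: haplotype frequencies are the expected haplotype counts over 2n.

Initialization is at linkage equilibrium (products of sample allele
frequencies), which deterministically breaks ties between symmetric
optima. Convergence is max |Δp| < 1e-9 or 1000 iterations; the
log-likelihood trajectory is retained and asserted non-decreasing in the
tests. D' is signed internally and exported as |D'| (the sign depends on
arbitrary allele labelling); D' = 0 at D = 0 by convention. Monomorphic
loci have undefined r² and raise an excluded-pair signal instead of
reporting 0.

Windowed LD computes every same-sequence pair within 100 kb (inclusive)
for populations of at least 40 samples, discards r² < 0.05, and the
stored table feeds tag-SNP selection; arbitrary pairs can still be
computed on demand through `em_haplotypes`.

## Tag-SNP selection

Variants are processed in MAF-descending order; each still-retained
variant removes every other retained variant within the window whose
pairwise stored r² exceeds 0.99 and whose MAF is lower. MAF ties break by
ascending genomic position (the earlier variant wins), making the greedy
procedure deterministic; the source procedure does not specify the tie
case. Survivors are reported in position order.

## Synthetic-data generator

The generator emulates capillary-style resequencing of one diploid
individual: 500 bp reads tiled at ~8× over a 4.1 kb region with small
placement jitter, base qualities ~N(34, 4) floored at 20, a 0.001
per-base error rate with errors assigned low qualities (5–15), and
properly paired mates. Planted heterozygous SNPs alternate between
alleles across overlapping reads (~50% alternative), carry a clean
quality of 35 unless a test forces a lower one, and are protected by a
±10 bp error-free guard zone so the planted truth is exactly recoverable
under the stated thresholds. Population panels draw two haplotypes per
sample per two-SNP block from fixed haplotype frequencies (defaults:
complete LD, equilibrium, and an intermediate block; 60 samples; 1%
missingness).

The fixture gene models are hand-placed, not sampled: specific codons are
pinned at and away from splice junctions so an exhaustive substitution
sweep reaches every substitution-reachable consequence class, including a
biologically artificial in-frame stop codon 2 bp into an exon whose only
purpose is to make the splice-flavoured stop-loss class reachable.
Mature-miRNA intervals are written as `mature_miRNA` GTF features — there
is no standard GTF encoding for them — and read back by the bundled
parser.

What the generator does not emulate: mapping ambiguity, indel sequencing
errors, quality miscalibration, correlated errors, coalescent population
structure (LD is blockwise-pairwise only), and multi-individual read
sets. Passing tests therefore demonstrate rule fidelity and estimator
correctness under clean conditions, not robustness to real-data artefacts.

## Problem sizes

The test suite and the acceptance script run on deliberately small
problems chosen to exercise every rule edge: a 30 kb genome, ~66 reads,
exhaustive ±5.1 kb substitution sweeps (~39k classifications), 40-sample
LD tables against a grid-search oracle, 200 replicate 1000-sample panels
for D' recovery, and tag-SNP instances of up to 10 SNPs checked against a
literal re-implementation of the greedy procedure.

## Known limitations

* No realignment, base-quality recalibration, or genotype likelihoods;
  the caller is a rule system, not a probabilistic model.
* SAM support is a read-only subset (M/=/X/I/D/S); BAM/CRAM are not read.
* Biallelic loci only in the genotype matrix; multi-allelic VCF rows are
  skipped for LD.
* Two-locus haplotypes only; no multi-locus phasing.
* Transcript models assume complete terminal codons and no trans-splicing;
  incomplete codons are truncated.
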