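"""Pairwise LD from unphased genotypes and tag-SNP selection.

Simulates a 500-sample population with three two-SNP blocks of known
haplotype frequencies, estimates r2 and |D'| with the EM algorithm, and
prunes the panel down to tag SNPs: within a 100 kb window, any variant in
near-perfect LD (r2 > 0.99) with a higher-MAF variant is dropped.
"""

from varkit.fixtures import FixtureSpec, make_genome_and_annotation, make_genotypes
from varkit.popgen_ld import maf, select_tag_snps, windowed_ld

spec = FixtureSpec(seed=1, n_samples=500)
genome, _, _ = make_genome_and_annotation(spec)
g, truth = make_genotypes(spec, genome)

print(f"population {g.population_id}: {len(g.samples)} samples, "
      f"{len(g.variants)} SNPs")
print("\ntarget blocks (p_AB, p_Ab, p_aB, p_ab):")
for b in truth:
    print(f"  {b['id1']}-{b['id2']}: {b['p']}")

stored = windowed_ld(g)  # pairs with r2 >= 0.05 within 100 kb
print("\nstored LD pairs (r2 >= 0.05):")
for r in stored:
    print(f"  {r.id1}-{r.id2}: r2={r.r2:.3f} |D'|={r.abs_d_prime:.3f} n={r.n_informative}")

tags = select_tag_snps(g, stored)
mafs = {v.id: maf(g, k) for k, v in enumerate(g.variants)}
print(f"\ntag SNPs ({len(tags)} of {len(g.variants)}):")
for t in tags:
    print(f"  {t} (MAF {mafs[t]:.2f})")
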