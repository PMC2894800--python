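"""Population-genetic post-processing: MAF, pairwise LD, tag SNPs.

Two-locus linkage disequilibrium is estimated from unphased diploid
genotypes with the standard EM algorithm: only double heterozygotes are
phase-ambiguous, and the E-step splits them between the coupling (AB/ab)
and repulsion (Ab/aB) configurations in proportion to the current haplotype
frequencies. From the fitted frequencies, D = p_AB - p_A p_B, D' = D/D_max
with the usual frequency-constrained maximum, and r^2 = D^2/(p_A p_a p_B p_b).

Pairwise LD is computed within a 100 kb window for populations of at least
40 samples, values below r^2 = 0.05 are discarded, and the stored table
feeds greedy tag-SNP selection: variants are ranked by MAF (highest first)
and any retained variant removes lower-MAF partners with r^2 > 0.99 inside
the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import cyvcf2
import numpy as np

from .errors import ContractError, ValidationError

MISSING = -1  # genotype code for a missing call

#: defaults of the LD/tag-SNP post-processing
LD_WINDOW_BP = 100_000
MIN_R2_STORE = 0.05
MIN_LD_SAMPLES = 40
TAG_R2_CUT = 0.99


class MonomorphicLocus(ValidationError):
    """Raised when LD is requested for a locus with a single allele."""


@dataclass
class VariantSite:
    id: str
    seq_name: str
    pos: int
    ref: str = "A"
    alt: str = "a"


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes for one population.

    ``genotypes`` is an (n_samples, n_variants) int8 array counting ALT
    alleles: 0 = ref/ref, 1 = het, 2 = alt/alt, -1 = missing. Only biallelic
    variants are representable.
    """

    population_id: str
    samples: list[str]
    variants: list[VariantSite]
    genotypes: np.ndarray

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ContractError(
                f"genotype table is {self.genotypes.shape}, expected "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = set(np.unique(self.genotypes)) - {-1, 0, 1, 2}
        if bad:
            raise ContractError(f"invalid genotype codes {sorted(bad)}")

    @classmethod
    def from_vcf(
        cls,
        path: str,
        population_id: str = "ALL",
        samples: list[str] | None = None,
    ) -> "GenotypeMatrix":
        """Load genotype columns from a VCF; biallelic sites only.

        cyvcf2 genotype classes map to ALT-allele counts; unknown genotypes
        become missing. ``samples`` restricts (and orders) the population.
        """
        vcf = cyvcf2.VCF(str(path), samples=samples)
        names = list(vcf.samples)
        sites, columns = [], []
        for v in vcf:
            if len(v.ALT) != 1:
                continue
            sites.append(
                VariantSite(v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.REF, v.ALT[0])
            )
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            g = np.array(v.gt_types)
            col = np.where(g == 3, 2, np.where(g == 2, MISSING, g))
            columns.append(col.astype(np.int8))
        geno = (
            np.stack(columns, axis=1)
            if columns
            else np.zeros((len(names), 0), dtype=np.int8)
        )
        return cls(population_id, names, sites, geno)


@dataclass
class LDResult:
    """Pairwise LD between two loci, from EM haplotype frequencies."""

    id1: str
    id2: str
    p_ab: tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)
    d: float
    d_prime: float  # signed; export |D'|
    r2: float
    n_informative: int
    logliks: list[float] = field(default_factory=list, repr=False)

    @property
    def abs_d_prime(self) -> float:
        return abs(self.d_prime)


# ---------------------------------------------------------------------------
# MAF


def maf(g: GenotypeMatrix, variant_index: int) -> float:
    """Minor-allele frequency at one site: minor count / (2 x non-missing)."""
    col = g.genotypes[:, variant_index]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValidationError(
            f"MAF undefined for {g.variants[variant_index].id}: all genotypes missing"
        )
    alt = int(obs.sum())
    total = 2 * int(obs.size)
    return min(alt, total - alt) / total


# ---------------------------------------------------------------------------
# two-locus EM


def _genotype_counts(col1: np.ndarray, col2: np.ndarray) -> np.ndarray:
    """3x3 table over ALT-allele counts, pairwise-complete samples only."""
    keep = (col1 != MISSING) & (col2 != MISSING)
    counts = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(col1[keep], col2[keep]):
        counts[a, b] += 1
    return counts


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    pAB, pAb, paB, pab = p
    prob = np.array(
        [
            [pAB**2, 2 * pAB * pAb, pAb**2],
            [2 * pAB * paB, 2 * pAB * pab + 2 * pAb * paB, 2 * pAb * pab],
            [paB**2, 2 * paB * pab, pab**2],
        ]
    )
    mask = counts > 0
    with np.errstate(divide="ignore"):
        logp = np.log(prob, where=mask, out=np.zeros_like(prob))
    if np.any(mask & (prob <= 0)):
        return -np.inf
    return float((counts * logp)[mask].sum())


def em_from_counts(
    counts: np.ndarray, tol: float = 1e-9, max_iter: int = 1000
) -> tuple[np.ndarray, list[float]]:
    """EM on a 3x3 genotype-pair count table.

    Returns haplotype frequencies (p_AB, p_Ab, p_aB, p_ab) — A/B denote the
    reference alleles — and the log-likelihood trajectory. Initialization is
    at linkage equilibrium so the deterministic start breaks ties between
    symmetric optima.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        raise ValidationError("no informative samples")
    # observed allele frequencies (margins are fully observed)
    alt1 = (counts * np.array([[0], [1], [2]])).sum() / (2 * n)
    alt2 = (counts * np.array([[0, 1, 2]])).sum() / (2 * n)
    pA, pB = 1 - alt1, 1 - alt2
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicLocus("both loci must be polymorphic")
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_dh = counts[1, 1]  # double heterozygotes: the only ambiguous class
    # fixed haplotype contributions from unambiguous genotype classes
    fixed = np.array(
        [
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # AB
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # Ab
            2 * counts[2, 0] + counts[1, 0] + counts[2, 1],  # aB
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # ab
        ],
        dtype=float,
    )
    logliks = [_loglik(counts, p)]
    for _ in range(max_iter):
        denom = p[0] * p[3] + p[1] * p[2]
        pi = 0.5 if denom == 0 else p[0] * p[3] / denom
        hap = fixed + n_dh * np.array([pi, 1 - pi, 1 - pi, pi])
        new_p = hap / (2 * n)
        logliks.append(_loglik(counts, new_p))
        delta = np.max(np.abs(new_p - p))
        p = new_p
        if delta < tol:
            break
    return p, logliks


def ld_from_frequencies(p: np.ndarray) -> tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""
    pAB, pAb, paB, pab = p
    pA, pB = pAB + pAb, pAB + paB
    pa, pb = 1 - pA, 1 - pB
    d = pAB - pA * pB
    if d > 0:
        dmax = min(pA * pb, pa * pB)
    elif d < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        return 0.0, 0.0, 0.0
    d_prime = d / dmax if dmax > 0 else 0.0
    denom = pA * pa * pB * pb
    r2 = d * d / denom if denom > 0 else 0.0
    return d, d_prime, r2


def em_haplotypes(
    g: GenotypeMatrix,
    i: int,
    j: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> LDResult:
    """EM haplotype-frequency estimate and LD statistics for two loci.

    Uses pairwise-complete samples; raises MonomorphicLocus when either
    locus has a single allele among them (r^2 is undefined there).
    """
    counts = _genotype_counts(g.genotypes[:, i], g.genotypes[:, j])
    n_inf = int(counts.sum())
    p, logliks = em_from_counts(counts, tol=tol, max_iter=max_iter)
    d, d_prime, r2 = ld_from_frequencies(p)
    return LDResult(
        id1=g.variants[i].id,
        id2=g.variants[j].id,
        p_ab=tuple(float(x) for x in p),
        d=d,
        d_prime=d_prime,
        r2=r2,
        n_informative=n_inf,
        logliks=logliks,
    )


# ---------------------------------------------------------------------------
# windowed LD table and tag-SNP selection


def windowed_ld(
    g: GenotypeMatrix,
    window: int = LD_WINDOW_BP,
    min_r2_store: float = MIN_R2_STORE,
    min_samples: int = MIN_LD_SAMPLES,
) -> list[LDResult]:
    """All-pairs LD within a genomic window, thresholded for storage.

    Populations smaller than ``min_samples`` yield an empty table (with a
    warning); pairs with r^2 below ``min_r2_store`` are discarded, and
    monomorphic loci are skipped.
    """
    if len(g.samples) < min_samples:
        warnings.warn(
            f"population {g.population_id} has {len(g.samples)} samples "
            f"(< {min_samples}); no LD computed",
            stacklevel=2,
        )
        return []
    order = sorted(
        range(len(g.variants)), key=lambda k: (g.variants[k].seq_name, g.variants[k].pos)
    )
    out: list[LDResult] = []
    for a in range(len(order)):
        i = order[a]
        vi = g.variants[i]
        for b in range(a + 1, len(order)):
            j = order[b]
            vj = g.variants[j]
            if vj.seq_name != vi.seq_name:
                break
            if vj.pos - vi.pos > window:
                break
            try:
                res = em_haplotypes(g, i, j)
            except (MonomorphicLocus, ValidationError):
                continue
            if res.r2 >= min_r2_store:
                out.append(res)
    return out


def select_tag_snps(
    g: GenotypeMatrix,
    ld: list[LDResult],
    r2_cut: float = TAG_R2_CUT,
    window: int = LD_WINDOW_BP,
) -> list[str]:
    """Greedy tag-SNP selection from the stored LD table.

    Variants are processed in MAF-descending order (ties by ascending
    position); each still-retained variant removes every other retained
    variant within the window whose pairwise r^2 exceeds ``r2_cut`` and
    whose MAF is lower (at equal MAF, the later-positioned variant is
    removed). Survivors, in position order, are the tag SNPs.
    """
    n = len(g.variants)
    freq = {}
    for k in range(n):
        try:
            freq[k] = maf(g, k)
        except ValidationError:
            freq[k] = 0.0
    pos = {k: (g.variants[k].seq_name, g.variants[k].pos) for k in range(n)}
    r2: dict[tuple[str, str], float] = {}
    for res in ld:
        r2[(res.id1, res.id2)] = res.r2
        r2[(res.id2, res.id1)] = res.r2
    order = sorted(range(n), key=lambda k: (-freq[k], pos[k]))
    priority = {k: rank for rank, k in enumerate(order)}
    retained = set(range(n))
    for k in order:
        if k not in retained:
            continue
        vid = g.variants[k].id
        for m in sorted(retained - {k}):
            if pos[m][0] != pos[k][0] or abs(pos[m][1] - pos[k][1]) > window:
                continue
            pair_r2 = r2.get((vid, g.variants[m].id))
            if pair_r2 is not None and pair_r2 > r2_cut and priority[m] > priority[k]:
                retained.discard(m)
    survivors = sorted(retained, key=lambda k: pos[k])
    return [g.variants[k].id for k in survivors]


def write_ld_tsv(ld: list[LDResult], g: GenotypeMatrix, path: str) -> None:
    """LD table as TSV: id1, id2, distance, D, |D'|, r2, n."""
    pos = {v.id: (v.seq_name, v.pos) for v in g.variants}
    with open(path, "w") as fh:
        fh.write("id1\tid2\tdistance\tD\tD_prime\tr2\tn\n")
        for res in ld:
            dist = abs(pos[res.id1][1] - pos[res.id2][1])
            fh.write(
                f"{res.id1}\t{res.id2}\t{dist}\t{res.d:.6f}\t"
                f"{res.abs_d_prime:.6f}\t{res.r2:.6f}\t{res.n_informative}\n"
            )


def write_haploview(ld: list[LDResult], path: str) -> None:
    """Pairwise values in the Haploview text-LD column layout."""
    with open(path, "w") as fh:
        fh.write("L1\tL2\tD'\tLOD\tr^2\tCIlow\tCIhi\tDist\tT-int\n")
        for res in ld:
            fh.write(
                f"{res.id1}\t{res.id2}\t{res.abs_d_prime:.3f}\t0.0\t"
                f"{res.r2:.3f}\t0.0\t1.0\t0\t0\n"
            )
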