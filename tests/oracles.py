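"""Independent brute-force re-implementations used as test oracles.

Each function here recomputes a result from the rule statements directly —
per-base scans, literal per-column filters, grid searches — sharing no code
path with the library implementations they check.
"""

from __future__ import annotations

import numpy as np

# hand-written standard genetic code (independent of the library's translation)
_CODE = {}
_B = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _a in enumerate(_AA):
    _CODE[_B[_i // 16] + _B[(_i // 4) % 4] + _B[_i % 4]] = _a

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _translate(codon: str) -> str:
    return _CODE.get(codon.upper(), "X")


# ---------------------------------------------------------------------------
# consequence classification, per-base


def bf_consequence(pos: int, ref: str, alt: str, t, genome) -> str:
    """Classify a SNV against one transcript by direct scanning."""
    span_lo = min(s for s, _ in t.exons)
    span_hi = max(e for _, e in t.exons)
    if pos < span_lo - 5000 or pos > span_hi + 5000:
        return "Intergenic"
    if pos < span_lo:
        return "Upstream" if t.strand == +1 else "Downstream"
    if pos > span_hi:
        return "Downstream" if t.strand == +1 else "Upstream"
    if not t.is_coding:
        for s, e in t.mature_mirna:
            if s <= pos <= e:
                return "Within mature miRNA"
        return "Within non-coding gene"
    exonic = any(s <= pos <= e for s, e in t.exons)
    if not exonic:
        # intron distance: scan every intron base
        d = None
        exs = sorted(t.exons)
        for k in range(len(exs) - 1):
            istart, iend = exs[k][1] + 1, exs[k + 1][0] - 1
            if istart <= pos <= iend:
                d = min(pos - istart + 1, iend - pos + 1)
        assert d is not None
        if d <= 2:
            return "Essential splice site, intronic"
        if d <= 8:
            return "Splice site, intronic"
        return "Intronic"
    # exon-edge distance, counted only from intron-adjacent boundaries
    exs = sorted(t.exons)
    edge_d = None
    for k, (s, e) in enumerate(exs):
        if s <= pos <= e:
            ds = []
            if k > 0:
                ds.append(pos - s + 1)
            if k < len(exs) - 1:
                ds.append(e - pos + 1)
            if ds:
                edge_d = min(ds)
    splice = edge_d is not None and edge_d <= 3
    # spliced CDS walk
    exonic_positions = [p for s, e in exs for p in range(s, e + 1)]
    if t.strand == -1:
        exonic_positions = exonic_positions[::-1]
    cds_positions = [p for p in exonic_positions if t.cds_start <= p <= t.cds_end]
    if pos not in cds_positions:
        before = pos < t.cds_start
        five = before if t.strand == +1 else not before
        if five:
            return "Splice site, 5' UTR" if splice else "5' UTR"
        return "Splice site, 3' UTR" if splice else "3' UTR"
    idx = cds_positions.index(pos)
    codon_pos = cds_positions[idx - idx % 3 : idx - idx % 3 + 3]
    if len(codon_pos) < 3:
        ref_aa = alt_aa = "X"
    else:
        bases = [genome.base(t.seq_name, p) for p in codon_pos]
        alt_bases = [alt if p == pos else b for p, b in zip(codon_pos, bases)]
        if t.strand == -1:
            bases = [_RC[b] for b in bases]
            alt_bases = [_RC[b] for b in alt_bases]
        ref_aa = _translate("".join(bases))
        alt_aa = _translate("".join(alt_bases))
    if alt_aa == "*" and ref_aa != "*":
        return "Stop gained, splice site" if splice else "Stop gained"
    if ref_aa == "*" and alt_aa != "*":
        return "Stop lost, splice site" if splice else "Stop lost"
    if ref_aa == alt_aa and ref_aa != "X":
        return "Splice site, synonymous coding" if splice else "Synonymous coding"
    return "Non-Synonymous coding, splice site" if splice else "Non-synonymous coding"


# ---------------------------------------------------------------------------
# literal-rule SNP caller


def _columns(read, genome):
    """(ref_pos -> (read_offset, base, matches)) for aligned M bases."""
    cols = {}
    roff, rpos = 0, read.start
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                base = read.read_seq[roff + i]
                cols[rpos + i] = (roff + i, base, base == genome.base(read.seq_name, rpos + i))
            roff += n
            rpos += n
        elif op in "IS":
            roff += n
        elif op == "D":
            rpos += n
    return cols


def _bf_nqs(read, cols, ref_pos, cfg):
    off, base, _match = cols[ref_pos]
    if read.quals[off] < cfg.min_variant_phred:
        return False
    # read-axis flank categories
    cats = {}
    roff, rpos = 0, read.start
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                cats[roff + i] = (
                    "match" if cols[rpos + i][2] else "mismatch"
                )
            roff += n
            rpos += n
        elif op in "IS":
            for i in range(n):
                cats[roff + i] = "ins" if op == "I" else "clip"
            roff += n
        elif op == "D":
            rpos += n
    for d in range(1, cfg.exact_flank_bp + 1):
        for o in (off - d, off + d):
            if o not in cats or cats[o] != "match":
                return False
            if read.quals[o] <= cfg.min_flank_phred:
                return False
    mism = 0
    for o in range(off - cfg.mismatch_window_bp, off + cfg.mismatch_window_bp + 1):
        if o == off or o not in cats:
            continue
        if cats[o] in ("mismatch", "ins"):
            mism += 1
    return mism <= cfg.max_flank_mismatches


def bf_call_snps(reads, genome, cfg, genome_coverage=1.0):
    """Literal application of the published filtering rules, per column.

    Returns {(seq, pos, individual): {allele: count}} for emitted calls.
    """
    max_mm, max_depth = cfg.max_read_mismatches, cfg.max_site_depth
    if genome_coverage < cfg.low_coverage_threshold:
        max_mm = max(1, int(max_mm * cfg.low_coverage_scale))
        max_depth = max(1, int(max_depth * cfg.low_coverage_scale))
    kept = []
    for read in reads:
        if read.mate_status == "improperly_paired":
            continue
        cols = _columns(read, genome)
        if sum(1 for _o, _b, m in cols.values() if not m) > max_mm:
            continue
        kept.append((read, cols))
    positions = sorted(
        {(r.seq_name, p) for r, cols in kept for p in cols}
    )
    out = {}
    for seq, pos in positions:
        covering = [(r, c) for r, c in kept if r.seq_name == seq and pos in c]
        if not any(not c[pos][2] for _r, c in covering):
            continue  # no mismatch here
        if len(covering) > max_depth:
            continue
        by_ind = {}
        for r, c in covering:
            if _bf_nqs(r, c, pos, cfg):
                by_ind.setdefault(r.individual, []).append(c[pos][1])
        if any(len(set(b)) > cfg.max_alleles_per_individual for b in by_ind.values()):
            continue
        ref = genome.base(seq, pos)
        for ind, bases in by_ind.items():
            if not any(b != ref for b in bases):
                continue
            if len(bases) >= cfg.min_depth_for_minor_rule:
                counts = {a: bases.count(a) for a in set(bases)}
                if min(counts.values()) < cfg.min_minor_reads:
                    continue
            out[(seq, pos, ind)] = {a: bases.count(a) for a in set(bases)}
    return out


# ---------------------------------------------------------------------------
# interval-sweep coverage oracle


def bf_coverage(reads, individual=None):
    per_seq = {}
    for r in reads:
        if individual is not None and r.individual != individual:
            continue
        end = r.start + sum(n for op, n in r.cigar if op in "M=XD") - 1
        per_seq.setdefault(r.seq_name, []).append((r.start, end))
    out = []
    for seq in sorted(per_seq):
        ivs = per_seq[seq]
        lo = min(s for s, _ in ivs)
        hi = max(e for _, e in ivs)
        depth = [sum(1 for s, e in ivs if s <= p <= e) for p in range(lo, hi + 1)]
        cls = ["0" if d == 0 else ("1" if d == 1 else "2+") for d in depth]
        start = 0
        for i in range(1, len(cls) + 1):
            if i == len(cls) or cls[i] != cls[start]:
                if cls[start] != "0":
                    out.append((seq, lo + start, lo + i - 1, cls[start]))
                start = i
    return out


# ---------------------------------------------------------------------------
# LD: 1-D grid-search maximum likelihood over p_AB


def grid_search_ld(counts: np.ndarray, step: float = 1e-3):
    """Maximum-likelihood haplotype frequencies by grid search.

    The allele-frequency margins are observed directly, so p_AB is the only
    free parameter; a coarse grid (``step``) is refined locally to pin the
    optimum. Returns (D, D', r2).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    pa = (counts * np.array([[0], [1], [2]])).sum() / (2 * n)
    pb = (counts * np.array([[0, 1, 2]])).sum() / (2 * n)
    pA, pB = 1 - pa, 1 - pb

    def loglik(pAB):
        p = np.array(
            [pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB]
        )
        if np.any(p < -1e-12):
            return -np.inf
        p = np.clip(p, 0, 1)
        prob = np.array(
            [
                [p[0] ** 2, 2 * p[0] * p[1], p[1] ** 2],
                [2 * p[0] * p[2], 2 * p[0] * p[3] + 2 * p[1] * p[2], 2 * p[1] * p[3]],
                [p[2] ** 2, 2 * p[2] * p[3], p[3] ** 2],
            ]
        )
        if np.any((counts > 0) & (prob <= 0)):
            return -np.inf
        with np.errstate(divide="ignore"):
            lp = np.where(prob > 0, np.log(np.where(prob > 0, prob, 1)), 0.0)
        return float((counts * lp).sum())

    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    grid = np.arange(lo, hi + step / 2, step)
    best = grid[int(np.argmax([loglik(x) for x in grid]))]
    width = step
    while width > 1e-8:
        fine = np.linspace(max(lo, best - width), min(hi, best + width), 41)
        best = fine[int(np.argmax([loglik(x) for x in fine]))]
        width /= 10
    d = best - pA * pB
    if d > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif d < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return 0.0, 0.0, 0.0
    denom = pA * (1 - pA) * pB * (1 - pB)
    return d, d / dmax if dmax > 0 else 0.0, d * d / denom if denom > 0 else 0.0


def count_haplotypes_unambiguous(col1, col2):
    """Direct haplotype counting; valid only without double heterozygotes."""
    counts = {"AB": 0, "Ab": 0, "aB": 0, "ab": 0}
    for g1, g2 in zip(col1, col2):
        if g1 < 0 or g2 < 0:
            continue
        assert not (g1 == 1 and g2 == 1), "ambiguous double heterozygote"
        l1 = ["A", "a"][g1 // 2] * 2 if g1 != 1 else "Aa"
        l2 = ["B", "b"][g2 // 2] * 2 if g2 != 1 else "Bb"
        for h1, h2 in zip(l1, l2):
            counts[h1 + h2] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# tag SNP greedy, literal


def bf_select_tags(positions, mafs, r2_lookup, r2_cut=0.99, window=100_000):
    """Literal greedy procedure on (index -> (seq, pos)), (index -> MAF).

    ``r2_lookup`` maps frozenset({i, j}) -> r2 for stored pairs. Ties in MAF
    are broken by ascending position (earlier position = higher priority).
    """
    order = sorted(positions, key=lambda k: (-mafs[k], positions[k]))
    rank = {k: i for i, k in enumerate(order)}
    alive = set(positions)
    for k in order:
        if k not in alive:
            continue
        for m in list(alive):
            if m == k:
                continue
            if positions[m][0] != positions[k][0]:
                continue
            if abs(positions[m][1] - positions[k][1]) > window:
                continue
            r2 = r2_lookup.get(frozenset({k, m}))
            if r2 is not None and r2 > r2_cut and rank[m] > rank[k]:
                alive.discard(m)
    return sorted(alive, key=lambda k: positions[k])
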