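"""Reference sequence and transcript structure.

All coordinate arithmetic used by the consequence engine lives here:
genomic <-> cDNA <-> CDS <-> protein mappings and the intron/exon boundary
offsets that drive splice-site classification.

Conventions
-----------
* Coordinates are 1-based, fully closed intervals on the forward genome
  strand. Insertions between two bases are written ``start = end + 1``.
* Exons are stored in ascending genomic order regardless of strand;
  transcript orientation is applied when walking spliced coordinates.
* Splice-boundary offsets are measured symmetrically: the distance reported
  is the minimum of the distances to the two edges of the enclosing intron
  (or to the intron-adjacent edges of the enclosing exon), so donor and
  acceptor ends behave identically. The terminal base of an intron, and the
  exon base abutting an intron, are both at offset 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import ContractError, CoordinateError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Offsets farther than this from a splice boundary are never splice-relevant.
MAX_EDGE_OFFSET = 8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon; any non-ACGT base yields the unknown residue X."""
    codon = codon.upper()
    if len(codon) != 3:
        return "X"
    if any(b not in "ACGT" for b in codon):
        return "X"
    return str(Seq(codon).translate())


@dataclass
class ReferenceGenome:
    """In-memory reference assembly: name -> uppercase nucleotide string."""

    sequences: dict[str, str]

    def __post_init__(self):
        clean = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ContractError(
                    f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.sequences = clean
        self.lengths = {name: len(seq) for name, seq in clean.items()}

    def fetch(self, seq_name: str, start: int, end: int) -> str:
        """Bases in [start, end], 1-based inclusive."""
        if seq_name not in self.sequences:
            raise CoordinateError(f"unknown sequence {seq_name!r}")
        if start < 1 or end > self.lengths[seq_name] or start > end + 1:
            raise CoordinateError(
                f"{seq_name}:{start}-{end} outside 1..{self.lengths[seq_name]}"
            )
        return self.sequences[seq_name][start - 1 : end]

    def base(self, seq_name: str, pos: int) -> str:
        return self.fetch(seq_name, pos, pos)


@dataclass
class RegulatoryFeature:
    """A regulatory interval, optionally linked to a gene."""

    seq_name: str
    start: int
    end: int
    linked_gene: str | None = None

    def __post_init__(self):
        if self.start > self.end:
            raise ContractError("regulatory feature start > end")


@dataclass
class TranscriptModel:
    """Strand-aware exon/CDS structure on one reference sequence.

    ``exons`` are (start, end) pairs in genomic coordinates, ascending and
    non-overlapping. ``cds_start``/``cds_end`` bound the translated region
    genomically (both None for non-coding transcripts). ``mature_mirna``
    lists the processed-product sub-intervals of a miRNA transcript.
    """

    id: str
    gene_id: str
    seq_name: str
    strand: int
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None
    biotype: str = "protein_coding"
    mature_mirna: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in (+1, -1):
            raise ContractError(f"strand must be +1/-1, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ContractError(f"exon {s}-{e} has start > end")
            if prev_end is not None and s <= prev_end + 1:
                raise ContractError("exons overlap or introns have length < 1")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ContractError("cds_start and cds_end must be set together")
        if self.is_coding:
            if not (self.contains(self.cds_start) and self.contains(self.cds_end)):
                raise ContractError("CDS bounds must lie inside the exon union")
            if len(self.cds_genomic_positions()) < 3:
                raise ContractError("spliced CDS shorter than one codon")

    # -- basic geometry ----------------------------------------------------

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def exon_index_at(self, pos: int) -> int | None:
        """Genomic-order exon index (0-based) containing pos, else None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    # -- splice-boundary offsets ------------------------------------------

    def intron_offset(self, pos: int) -> tuple[int, int] | None:
        """(intron number in transcript orientation, distance from the nearest
        intron edge) for an intronic position; None if pos is not intronic.

        The terminal intron base is at distance 1, so the essential splice
        region ("first 2 or last 2" intron bases) is distance <= 2.
        """
        introns = self.introns
        for gi, (s, e) in enumerate(introns):
            if s <= pos <= e:
                d = min(pos - s + 1, e - pos + 1)
                number = gi + 1 if self.strand == +1 else len(introns) - gi
                return number, d
        return None

    def exon_edge_offset(self, pos: int) -> int | None:
        """Distance (1-based) from pos to the nearest intron-adjacent edge of
        its exon; None if pos is not exonic, farther than MAX_EDGE_OFFSET from
        every such edge, or the exon has no intron-adjacent edge.

        Transcript-terminal exon edges do not abut an intron and are ignored.
        """
        idx = self.exon_index_at(pos)
        if idx is None:
            return None
        s, e = self.exons[idx]
        candidates = []
        if idx > 0:  # left edge abuts the upstream (genomic) intron
            candidates.append(pos - s + 1)
        if idx < len(self.exons) - 1:  # right edge abuts an intron
            candidates.append(e - pos + 1)
        if not candidates:
            return None
        d = min(candidates)
        return d if d <= MAX_EDGE_OFFSET else None

    # -- spliced coordinate walks -----------------------------------------

    def exonic_positions(self) -> list[int]:
        """All exonic genomic positions in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return pos if self.strand == +1 else pos[::-1]

    def cds_genomic_positions(self) -> list[int]:
        """Genomic positions of the spliced CDS in transcript order."""
        if not self.is_coding:
            return []
        lo, hi = self.cds_start, self.cds_end
        return [p for p in self.exonic_positions() if lo <= p <= hi]

    def genomic_to_cdna(self, pos: int) -> int | None:
        """1-based position in the spliced transcript, or None if intronic."""
        if not self.contains(pos):
            return None
        if self.strand == +1:
            n = sum(
                min(e, pos) - s + 1 for s, e in self.exons if s <= pos
            )
        else:
            n = sum(
                e - max(s, pos) + 1 for s, e in self.exons if e >= pos
            )
        return n

    def genomic_to_cds(self, pos: int) -> tuple[int, int, int] | None:
        """(CDS position 1-based, codon index 1-based, within-codon offset 0-2)
        or None if pos is outside the spliced CDS."""
        if not self.is_coding:
            raise ContractError(f"transcript {self.id} is non-coding")
        cds = self.cds_genomic_positions()
        try:
            i = cds.index(pos)
        except ValueError:
            return None
        p = i + 1
        return p, (p - 1) // 3 + 1, (p - 1) % 3

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of genomic_to_cds for the position component."""
        cds = self.cds_genomic_positions()
        if not 1 <= cds_pos <= len(cds):
            raise CoordinateError(f"CDS position {cds_pos} outside 1..{len(cds)}")
        return cds[cds_pos - 1]

    def codon_at(self, codon_index: int, genome: ReferenceGenome) -> str:
        """Reference codon (transcript orientation) for a 1-based codon index."""
        cds = self.cds_genomic_positions()
        lo = (codon_index - 1) * 3
        bases = cds[lo : lo + 3]
        if len(bases) < 3:
            return ""  # incomplete terminal codon: truncated
        seq = "".join(genome.base(self.seq_name, p) for p in bases)
        if self.strand == -1:
            # positions are already in transcript order; complement only
            seq = seq.translate(_COMPLEMENT)
        return seq

    def cds_region(self, pos: int) -> str | None:
        """Classify an exonic position as '5utr' | 'cds' | '3utr'.

        Returns None for intronic positions; for non-coding transcripts every
        exonic position reports 'noncoding'.
        """
        if not self.contains(pos):
            return None
        if not self.is_coding:
            return "noncoding"
        if self.cds_start <= pos <= self.cds_end:
            return "cds"
        before_cds = pos < self.cds_start
        five_prime = before_cds if self.strand == +1 else not before_cds
        return "5utr" if five_prime else "3utr"
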