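"""Readers and writers for the standard formats the toolkit touches.

FASTA is read with Biopython, SAM with pysam, VCF with cyvcf2 and GTF/GFF3
with gffutils; a plain-text aligned-read table is supported as a SAM
alternative, and coverage is dumped as a simple two-class TSV.

Variant coordinates follow the toolkit convention: 1-based closed intervals,
with insertions written ``start = end + 1`` and empty alleles as "".
VCF's shared-leading-base indel style is converted on read and restored on
write.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import cyvcf2
import gffutils
import pysam
from Bio import SeqIO

from .errors import ContractError, FormatError, ValidationError
from .genome_model import ReferenceGenome, RegulatoryFeature, TranscriptModel

# ---------------------------------------------------------------------------
# domain records


@dataclass
class VariantRecord:
    """A located allele set, possibly multi-allelic, as reported by a source."""

    seq_name: str
    start: int
    end: int
    ref_allele: str
    alt_alleles: list[str]
    id: str = "."
    synonyms: list[str] = field(default_factory=list)
    source: str = "unknown"
    strand: int = +1  # strand of report

    def __post_init__(self):
        if not self.alt_alleles:
            raise ContractError(f"variant {self.id}: no alternative alleles")
        if any(a == self.ref_allele for a in self.alt_alleles):
            raise ContractError(f"variant {self.id}: alt equals ref")

    @property
    def is_insertion(self) -> bool:
        return self.start == self.end + 1

    @property
    def alleles(self) -> list[str]:
        return [self.ref_allele] + list(self.alt_alleles)


MATE_PROPER = "properly_paired"
MATE_IMPROPER = "improperly_paired"
MATE_UNPAIRED = "unpaired"

_CIGAR_OPS = "M=XIDS"


@dataclass
class AlignedRead:
    """One aligned read with per-base PHRED qualities.

    ``cigar`` is a list of (op, length) runs using ops M/=/X/I/D/S; M, = and
    X consume both axes, I and S only the read, D only the reference.
    """

    read_id: str
    seq_name: str
    start: int  # 1-based leftmost aligned reference base
    read_seq: str
    quals: list[int]
    cigar: list[tuple[str, int]]
    mate_status: str = MATE_UNPAIRED
    individual: str = "default"

    def __post_init__(self):
        if len(self.quals) != len(self.read_seq):
            raise ContractError(f"read {self.read_id}: qual/seq length mismatch")
        bad = [op for op, _ in self.cigar if op not in _CIGAR_OPS]
        if bad:
            raise ContractError(f"read {self.read_id}: unsupported CIGAR ops {bad}")
        read_len = sum(n for op, n in self.cigar if op in "M=XIS")
        if read_len != len(self.read_seq):
            raise ContractError(
                f"read {self.read_id}: CIGAR read-axis length {read_len} "
                f"!= sequence length {len(self.read_seq)}"
            )

    def aligned_pairs(self) -> list[tuple[int, int]]:
        """(read_offset 0-based, ref_pos 1-based) for every M/=/X base."""
        pairs = []
        roff, rpos = 0, self.start
        for op, n in self.cigar:
            if op in "M=X":
                pairs.extend((roff + i, rpos + i) for i in range(n))
                roff += n
                rpos += n
            elif op in "IS":
                roff += n
            elif op == "D":
                rpos += n
        return pairs

    def ref_end(self) -> int:
        """1-based rightmost reference base consumed by the alignment."""
        return self.start + sum(n for op, n in self.cigar if op in "M=XD") - 1


# ---------------------------------------------------------------------------
# FASTA / GTF / BED


def read_fasta(path: str) -> ReferenceGenome:
    """Multi-record FASTA (wrapped lines, case-insensitive) -> ReferenceGenome."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return ReferenceGenome(seqs)


def write_fasta(genome: ReferenceGenome, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _tx_attr(feature, *keys) -> str | None:
    for key in keys:
        if key in feature.attributes:
            val = feature.attributes[key][0]
            # GFF3 style "transcript:ENST..." prefixes
            return val.split(":", 1)[-1] if ":" in val else val
    return None


def read_transcripts(path: str) -> list[TranscriptModel]:
    """Build TranscriptModel objects from a GTF or GFF3 file.

    Uses exon and CDS features; optional ``mature_miRNA`` features mark the
    processed sub-intervals of miRNA transcripts. The biotype is taken from
    transcript_biotype/gene_biotype attributes when present, else inferred
    from CDS presence.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    mirna: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    for f in db.all_features():
        tid = _tx_attr(f, "transcript_id", "Parent")
        if tid is None:
            continue
        if f.featuretype not in ("exon", "CDS", "mature_miRNA"):
            continue
        meta.setdefault(
            tid,
            {
                "seq_name": f.seqid,
                "strand": +1 if f.strand != "-" else -1,
                "gene_id": _tx_attr(f, "gene_id") or tid,
                "biotype": _tx_attr(f, "transcript_biotype", "gene_biotype", "biotype"),
            },
        )
        target = {"exon": exons, "CDS": cds, "mature_miRNA": mirna}[f.featuretype]
        target.setdefault(tid, []).append((f.start, f.end))
    out = []
    for tid, m in meta.items():
        if tid not in exons:
            raise FormatError(f"transcript {tid} has no exon features")
        cds_ivs = cds.get(tid)
        cds_start = min(s for s, _ in cds_ivs) if cds_ivs else None
        cds_end = max(e for _, e in cds_ivs) if cds_ivs else None
        biotype = m["biotype"]
        if biotype is None:
            biotype = "protein_coding" if cds_ivs else "non_coding"
        if biotype not in ("protein_coding", "non_coding", "miRNA"):
            biotype = "protein_coding" if cds_ivs else "non_coding"
        out.append(
            TranscriptModel(
                id=tid,
                gene_id=m["gene_id"],
                seq_name=m["seq_name"],
                strand=m["strand"],
                exons=sorted(exons[tid]),
                cds_start=cds_start,
                cds_end=cds_end,
                biotype=biotype,
                mature_mirna=sorted(mirna.get(tid, [])),
            )
        )
    out.sort(key=lambda t: (t.seq_name, t.span[0], t.id))
    return out


def read_regulatory_bed(path: str) -> list[RegulatoryFeature]:
    """BED3+1 (0-based half-open, optional linked-gene column) -> features."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED row has fewer than 3 columns", lineno)
            seq, start0, end = parts[0], int(parts[1]), int(parts[2])
            gene = parts[3] if len(parts) > 3 and parts[3] != "." else None
            feats.append(RegulatoryFeature(seq, start0 + 1, end, gene))
    return feats


# ---------------------------------------------------------------------------
# VCF


def _normalize_vcf_alleles(
    pos: int, ref: str, alts: list[str]
) -> tuple[int, int, str, list[str]]:
    """Convert shared-leading-base indel style to internal coordinates."""
    if ref and alts and len({len(ref)} | {len(a) for a in alts}) > 1:
        if all(a and a[0] == ref[0] for a in alts):
            ref = ref[1:]
            alts = [a[1:] for a in alts]
            pos += 1
    start = pos
    end = pos + len(ref) - 1  # empty ref -> insertion, end = start - 1
    return start, end, ref, alts


def _prevalidate_vcf(path: str) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FormatError("VCF row has fewer than 8 columns", lineno)
            if not parts[1].isdigit():
                raise FormatError(f"VCF POS is not an integer: {parts[1]!r}", lineno)


def read_vcf(
    path: str, genome: ReferenceGenome | None = None, source: str = "vcf"
) -> list[VariantRecord]:
    """Read a VCF (plain or gzip) into VariantRecord objects.

    Multi-allelic rows are kept as a single record. When a genome is given,
    REF alleles are validated against it.
    """
    _prevalidate_vcf(path)
    records = []
    for v in cyvcf2.VCF(str(path)):
        start, end, ref, alts = _normalize_vcf_alleles(v.POS, v.REF, list(v.ALT))
        rec = VariantRecord(
            seq_name=v.CHROM,
            start=start,
            end=end,
            ref_allele=ref,
            alt_alleles=alts,
            id=v.ID or ".",
            source=source,
        )
        if genome is not None and ref:
            actual = genome.fetch(rec.seq_name, rec.start, rec.end)
            if actual != ref.upper():
                raise ValidationError(
                    f"variant {rec.id} at {rec.seq_name}:{rec.start}: REF "
                    f"{ref!r} does not match reference {actual!r}"
                )
        records.append(rec)
    return records


def write_vcf(
    records: list[VariantRecord],
    path: str,
    genome: ReferenceGenome | None = None,
    info: dict[int, str] | None = None,
    extra_header: list[str] = (),
) -> None:
    """Write VariantRecords as a sites-only VCF.

    Indels (empty internal alleles) are restored to the shared-leading-base
    VCF style, which requires the genome for the anchor base. ``info`` maps
    record index -> INFO string.
    """
    lines = ["##fileformat=VCFv4.2"]
    if genome is not None:
        lines.extend(
            f"##contig=<ID={name},length={genome.lengths[name]}>"
            for name in genome.sequences
        )
    else:
        lines.extend(
            f"##contig=<ID={name}>" for name in sorted({r.seq_name for r in records})
        )
    lines.extend(extra_header)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, rec in enumerate(sorted(records, key=lambda r: (r.seq_name, r.start))):
        pos, ref, alts = rec.start, rec.ref_allele, list(rec.alt_alleles)
        if ref == "" or any(a == "" for a in alts):
            if genome is None:
                raise ValidationError(
                    f"variant {rec.id}: writing an indel requires the genome "
                    "for the VCF anchor base"
                )
            anchor = genome.base(rec.seq_name, rec.start - 1)
            pos = rec.start - 1
            ref = anchor + ref
            alts = [anchor + a for a in alts]
        info_str = (info or {}).get(i, ".")
        lines.append(
            f"{rec.seq_name}\t{pos}\t{rec.id}\t{ref}\t{','.join(alts)}\t.\t.\t{info_str}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# aligned reads: SAM subset and plain-text table

_SAM_OP_NAMES = "MIDNSHP=X"


def read_sam(path: str, default_individual: str = "default") -> list[AlignedRead]:
    """Read a text SAM file into AlignedRead objects (subset: M/=/X/I/D/S).

    The individual is taken from the read-group (RG) tag when present. Hard
    clips are ignored; N/P ops are rejected.
    """
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.flag & 1:  # paired in sequencing
                status = MATE_PROPER if aln.flag & 2 else MATE_IMPROPER
            else:
                status = MATE_UNPAIRED
            cigar = []
            for op_code, n in aln.cigartuples or []:
                op = _SAM_OP_NAMES[op_code]
                if op == "H":
                    continue
                if op not in _CIGAR_OPS:
                    raise FormatError(
                        f"read {aln.query_name}: unsupported CIGAR op {op!r}"
                    )
                cigar.append((op, n))
            individual = (
                aln.get_tag("RG") if aln.has_tag("RG") else default_individual
            )
            reads.append(
                AlignedRead(
                    read_id=aln.query_name,
                    seq_name=aln.reference_name,
                    start=aln.reference_start + 1,
                    read_seq=aln.query_sequence.upper(),
                    quals=list(aln.query_qualities),
                    cigar=cigar,
                    mate_status=status,
                    individual=str(individual),
                )
            )
    return reads


_READS_TSV_COLUMNS = [
    "read_id",
    "individual",
    "seq_name",
    "start",
    "cigar",
    "read_seq",
    "quals",
    "mate_status",
]


def _parse_cigar_string(s: str) -> list[tuple[str, int]]:
    out, num = [], ""
    for ch in s:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise ValidationError(f"malformed CIGAR string {s!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise ValidationError(f"malformed CIGAR string {s!r}")
    return out


def read_reads_tsv(path: str) -> list[AlignedRead]:
    """Plain-text aligned-read table (SAM alternative).

    Tab-separated with header columns: read_id, individual, seq_name, start
    (1-based), cigar, read_seq, quals (PHRED+33 string), mate_status.
    """
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _READS_TSV_COLUMNS:
            raise FormatError(
                f"reads TSV header must be {_READS_TSV_COLUMNS}, got {header}", 1
            )
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_READS_TSV_COLUMNS):
                raise FormatError("reads TSV row has wrong column count", lineno)
            rid, ind, seq, start, cig, rseq, quals, mate = parts
            reads.append(
                AlignedRead(
                    read_id=rid,
                    seq_name=seq,
                    start=int(start),
                    read_seq=rseq.upper(),
                    quals=[ord(c) - 33 for c in quals],
                    cigar=_parse_cigar_string(cig),
                    mate_status=mate,
                    individual=ind,
                )
            )
    return reads


def write_reads_tsv(reads: list[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_READS_TSV_COLUMNS) + "\n")
        for r in reads:
            cig = "".join(f"{n}{op}" for op, n in r.cigar)
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        r.individual,
                        r.seq_name,
                        str(r.start),
                        cig,
                        r.read_seq,
                        quals,
                        r.mate_status,
                    ]
                )
                + "\n"
            )


def write_sam(
    reads: list[AlignedRead], genome: ReferenceGenome, path: str
) -> None:
    """Write AlignedReads as a text SAM file with @SQ/@RG header lines."""
    individuals = sorted({r.individual for r in reads})
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name in genome.sequences:
            fh.write(f"@SQ\tSN:{name}\tLN:{genome.lengths[name]}\n")
        for ind in individuals:
            fh.write(f"@RG\tID:{ind}\tSM:{ind}\n")
        for r in reads:
            if r.mate_status == MATE_UNPAIRED:
                flag = 0
            elif r.mate_status == MATE_PROPER:
                flag = 1 | 2
            else:
                flag = 1
            cig = "".join(f"{n}{op}" for op, n in r.cigar)
            quals = "".join(chr(q + 33) for q in r.quals)
            fh.write(
                "\t".join(
                    [
                        r.read_id,
                        str(flag),
                        r.seq_name,
                        str(r.start),
                        "60",
                        cig,
                        "*",
                        "0",
                        "0",
                        r.read_seq,
                        quals,
                        f"RG:Z:{r.individual}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# coverage dump

DEPTH_SINGLE = "1"
DEPTH_MULTI = "2+"


def write_coverage_tsv(
    ranges: list[tuple[str, int, int, str]], path: str
) -> None:
    """Write (seq, start, end, depth_class) ranges as a sorted TSV.

    Depth classes are "1" (single-read) and "2+" (at least two reads).
    Overlapping ranges are rejected.
    """
    rows = sorted(ranges, key=lambda r: (r[0], r[1]))
    prev: dict[str, int] = {}
    for seq, start, end, cls in rows:
        if cls not in (DEPTH_SINGLE, DEPTH_MULTI):
            raise ValidationError(f"bad depth class {cls!r}")
        if start > end:
            raise ValidationError(f"coverage range {seq}:{start}-{end} inverted")
        if seq in prev and start <= prev[seq]:
            raise ValidationError(f"overlapping coverage ranges on {seq} at {start}")
        prev[seq] = end
    with open(path, "w") as fh:
        fh.write("seq_name\tstart\tend\tdepth_class\n")
        for seq, start, end, cls in rows:
            fh.write(f"{seq}\t{start}\t{end}\t{cls}\n")


def read_coverage_tsv(path: str) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_name\t"):
            raise FormatError("missing coverage TSV header", 1)
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            seq, start, end, cls = line.rstrip("\n").split("\t")
            out.append((seq, int(start), int(end), cls))
    return out
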