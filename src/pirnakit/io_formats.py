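"""Readers and writers for the standard formats the pipeline touches.

Every coordinate that leaves this module is 0-based half-open
(``[start, end)``), regardless of the on-disk convention: BED is already
half-open, while RepeatMasker ``.out`` and GFF3 are 1-based inclusive and
are converted on read.  RNA bases (``U``) are normalized to DNA (``T``)
at parse time so downstream sequence comparisons are uniform.  All readers
accept plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from Bio import SeqIO

__all__ = [
    "ParseError",
    "GenomicInterval",
    "SmallRNARead",
    "AlignmentRecord",
    "TEConsensus",
    "MaskedInterval",
    "TranscriptModel",
    "read_small_rna_fasta",
    "read_small_rna_fastq",
    "read_genome_fasta",
    "write_genome_fasta",
    "write_reads_fastq",
    "read_te_consensus_fasta",
    "write_te_consensus_fasta",
    "read_repeatmasker_out",
    "read_masked_bed",
    "write_masked_bed",
    "read_gff3_transcripts",
    "write_transcripts_gff3",
    "read_alignments_bed",
    "write_alignments_bed",
    "read_domains_bed",
    "write_domains_bed",
    "write_clusters_bed",
    "read_clusters_bed",
    "revcomp",
]

PathLike = Union[str, Path]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


def _opener(path: PathLike) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic span, 0-based half-open, with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SmallRNARead:
    """A (possibly collapsed) small-RNA read with its library multiplicity."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1")
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One genomic placement of a read.

    ``n_genome_hits`` is the total number of placements of this read in the
    genome (1 for a genome-unique mapper).  The 5' end is the leftmost base
    for a plus-strand placement and the rightmost base for a minus-strand
    placement.
    """

    read_id: str
    interval: GenomicInterval
    n_genome_hits: int = 1

    def __post_init__(self) -> None:
        if self.n_genome_hits < 1:
            raise ValueError("n_genome_hits must be >= 1")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("alignment strand must be + or -")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        """Genomic position (0-based) of the read's 5' end."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class TEConsensus:
    """A transposable-element consensus sequence with its classification."""

    name: str
    te_class: str
    te_family: str
    sequence: str


@dataclass(frozen=True)
class MaskedInterval:
    """A repeat-masked genomic copy of a TE."""

    interval: GenomicInterval
    te_name: str
    te_class: str = ""
    te_family: str = ""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exons plus an optional 3'-UTR.

    Exons are stored sorted by genomic coordinate regardless of strand;
    the mature (spliced) sequence of a minus-strand transcript is the
    reverse complement of the concatenated exon sequence.
    """

    gene_id: str
    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    utr3: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        for a, b in zip(exons, exons[1:]):
            if a.chrom != b.chrom:
                raise ValueError(f"{self.transcript_id}: exons span chromosomes")
            if b.start < a.end:
                raise ParseError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if self.utr3 is not None:
            if not any(e.contains(self.utr3) for e in exons):
                # UTR may span several exons; require containment in the union
                covered = sum(e.overlap_bp(self.utr3) for e in exons)
                if covered != len(self.utr3):
                    raise ParseError(
                        f"{self.transcript_id}: three_prime_UTR not contained "
                        "in the exon union"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


# ---------------------------------------------------------------------------
# Small-RNA FASTA / FASTQ
# ---------------------------------------------------------------------------

_SUFFIX_RE = re.compile(r"(?:_x(\d+)|-(\d+))$")


def _parse_count(identifier: str, dialect: str) -> int:
    if dialect == "none":
        return 1
    if dialect != "suffix":
        raise ValueError(f"unknown count dialect {dialect!r}")
    m = _SUFFIX_RE.search(identifier)
    if m is None:
        return 1
    n = int(m.group(1) or m.group(2))
    if n < 1:
        raise ParseError(f"non-positive count suffix on identifier {identifier!r}")
    return n


def _normalize_seq(raw: str, identifier: str, path: PathLike) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ParseError(
            f"{path}: read {identifier!r} has invalid characters {sorted(bad)}"
        )
    return seq


def read_small_rna_fasta(
    path: PathLike, count_dialect: str = "suffix"
) -> list[SmallRNARead]:
    """Read a small-RNA FASTA file.

    With ``count_dialect='suffix'`` a trailing ``_xN`` or ``-N`` on the
    identifier is parsed as the read's multiplicity (the common collapsed
    small-RNA convention); with ``'none'`` every record has count 1.
    """
    reads = []
    with _opener(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            count = _parse_count(rec.id, count_dialect)
            seq = _normalize_seq(str(rec.seq), rec.id, path)
            reads.append(SmallRNARead(id=rec.id, sequence=seq, count=count))
    return reads


def read_small_rna_fastq(
    path: PathLike, count_dialect: str = "suffix"
) -> list[SmallRNARead]:
    """Read a small-RNA FASTQ file (qualities are ignored)."""
    reads = []
    with _opener(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            count = _parse_count(rec.id, count_dialect)
            seq = _normalize_seq(str(rec.seq), rec.id, path)
            reads.append(SmallRNARead(id=rec.id, sequence=seq, count=count))
    return reads


def read_genome_fasta(path: PathLike) -> dict[str, str]:
    """Read a genome FASTA into a {chrom: uppercase sequence} dict."""
    with _opener(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_genome_fasta(genome: dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_reads_fastq(reads: Iterable[SmallRNARead], path: PathLike) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# TE consensus FASTA (RepeatMasker-style `name#class/family` headers)
# ---------------------------------------------------------------------------

def _split_te_header(header: str) -> tuple[str, str, str]:
    if "#" in header:
        name, classification = header.split("#", 1)
    else:
        name, classification = header, ""
    if "/" in classification:
        te_class, te_family = classification.split("/", 1)
    else:
        te_class, te_family = classification, ""
    return name, te_class, te_family


def read_te_consensus_fasta(path: PathLike) -> list[TEConsensus]:
    """Read TE consensus sequences with ``name#class/family`` headers."""
    out = []
    seen: set[str] = set()
    with _opener(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name, te_class, te_family = _split_te_header(rec.id)
            if name in seen:
                raise ParseError(f"{path}: duplicate TE consensus name {name!r}")
            seen.add(name)
            seq = _normalize_seq(str(rec.seq), rec.id, path)
            out.append(
                TEConsensus(
                    name=name, te_class=te_class, te_family=te_family, sequence=seq
                )
            )
    return out


def write_te_consensus_fasta(library: Iterable[TEConsensus], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for te in library:
            classification = te.te_class
            if te.te_family:
                classification += f"/{te.te_family}"
            header = f"{te.name}#{classification}" if classification else te.name
            fh.write(f">{header}\n{te.sequence}\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: PathLike) -> list[MaskedInterval]:
    """Parse a RepeatMasker ``.out`` annotation file.

    The layout is three header lines followed by whitespace-separated rows
    with 1-based inclusive query coordinates, converted here to 0-based
    half-open.  Orientation ``C`` (complement) becomes strand ``-``.
    """
    out = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score", "There were no")):
                continue  # header / empty-result sentinel
            fields = stripped.split()
            if len(fields) < 11:
                raise ParseError(
                    f"{path}:{lineno}: expected >=11 RepeatMasker columns, "
                    f"got {len(fields)}"
                )
            try:
                begin, end = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            strand = "-" if fields[8] == "C" else "+"
            te_name = fields[9]
            te_class, te_family = (fields[10].split("/", 1) + [""])[:2]
            out.append(
                MaskedInterval(
                    interval=GenomicInterval(fields[4], begin - 1, end, strand),
                    te_name=te_name,
                    te_class=te_class,
                    te_family=te_family,
                )
            )
    return out


def read_masked_bed(path: PathLike) -> list[MaskedInterval]:
    """Read masked intervals from BED6 with ``te_name#class/family`` names."""
    out = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6")
            name, te_class, te_family = _split_te_header(fields[3])
            out.append(
                MaskedInterval(
                    interval=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), fields[5]
                    ),
                    te_name=name,
                    te_class=te_class,
                    te_family=te_family,
                )
            )
    return out


def write_masked_bed(masked: Iterable[MaskedInterval], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for m in masked:
            classification = m.te_class + (f"/{m.te_family}" if m.te_family else "")
            name = f"{m.te_name}#{classification}" if classification else m.te_name
            fh.write(
                f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}\t"
                f"{name}\t0\t{m.interval.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 transcript models
# ---------------------------------------------------------------------------

def _gff3_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for item in raw.strip().rstrip(";").split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gff3_transcripts(path: PathLike) -> list[TranscriptModel]:
    """Build transcript models from GFF3 gene/mRNA/exon/three_prime_UTR rows.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Exons whose Parent cannot be resolved are skipped; overlapping exons
    within one transcript raise :class:`ParseError`.
    """
    mrna_gene: dict[str, str] = {}
    mrna_strand: dict[str, str] = {}
    mrna_order: list[str] = []
    exons: dict[str, list[GenomicInterval]] = {}
    utr3s: dict[str, list[GenomicInterval]] = {}

    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, raw_attrs = fields
            attrs = _gff3_attributes(raw_attrs)
            if ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                if tid is None:
                    raise ParseError(f"{path}:{lineno}: mRNA without ID")
                mrna_gene[tid] = attrs.get("Parent", tid)
                mrna_strand[tid] = strand
                mrna_order.append(tid)
            elif ftype in ("exon", "three_prime_UTR"):
                parents = attrs.get("Parent", "")
                iv = GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
                target = exons if ftype == "exon" else utr3s
                for parent in filter(None, parents.split(",")):
                    target.setdefault(parent, []).append(iv)

    models = []
    for tid in mrna_order:
        tx_exons = exons.get(tid)
        if not tx_exons:
            continue  # transcript with no exon rows: nothing to model
        utr3 = None
        if tid in utr3s:
            parts = sorted(utr3s[tid], key=lambda u: u.start)
            utr3 = GenomicInterval(
                parts[0].chrom, parts[0].start, parts[-1].end, mrna_strand[tid]
            )
        models.append(
            TranscriptModel(
                gene_id=mrna_gene[tid],
                transcript_id=tid,
                strand=mrna_strand[tid],
                exons=tuple(tx_exons),
                utr3=utr3,
            )
        )
    return models


# ---------------------------------------------------------------------------
# BED6: alignments, chromatin domains, clusters
# ---------------------------------------------------------------------------

def write_transcripts_gff3(
    transcripts: Iterable[TranscriptModel], path: PathLike, source: str = "pirnakit"
) -> None:
    """Write transcript models as GFF3 gene/mRNA/exon/three_prime_UTR rows."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        seen_genes: set[str] = set()
        for tx in transcripts:
            chrom = tx.chrom
            start1 = min(e.start for e in tx.exons) + 1
            end1 = max(e.end for e in tx.exons)
            if tx.gene_id not in seen_genes:
                seen_genes.add(tx.gene_id)
                fh.write(
                    f"{chrom}\t{source}\tgene\t{start1}\t{end1}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.gene_id}\n"
                )
            fh.write(
                f"{chrom}\t{source}\tmRNA\t{start1}\t{end1}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={tx.gene_id}\n"
            )
            for e in tx.exons:
                fh.write(
                    f"{chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{tx.strand}\t.\tParent={tx.transcript_id}\n"
                )
            if tx.utr3 is not None:
                fh.write(
                    f"{chrom}\t{source}\tthree_prime_UTR\t{tx.utr3.start + 1}\t"
                    f"{tx.utr3.end}\t.\t{tx.strand}\t.\tParent={tx.transcript_id}\n"
                )


def read_alignments_bed(path: PathLike) -> list[AlignmentRecord]:
    """Read read placements from BED6 (name = read id, score = genome hits)."""
    out = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
                hits = int(fields[4]) if fields[4] not in (".", "") else 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(
                AlignmentRecord(read_id=fields[3], interval=iv, n_genome_hits=max(hits, 1))
            )
    return out


def write_alignments_bed(alignments: Iterable[AlignmentRecord], path: PathLike) -> None:
    with open(path, "wt") as fh:
        for a in alignments:
            fh.write(
                f"{a.interval.chrom}\t{a.interval.start}\t{a.interval.end}\t"
                f"{a.read_id}\t{a.n_genome_hits}\t{a.interval.strand}\n"
            )


def read_domains_bed(path: PathLike) -> list[tuple[GenomicInterval, str]]:
    """Read chromatin-domain intervals; the BED name column is the class."""
    out = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
            out.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
            )
    return out


def write_domains_bed(
    domains: Iterable[tuple[GenomicInterval, str]], path: PathLike
) -> None:
    with open(path, "wt") as fh:
        for iv, label in domains:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t.\n")


def write_clusters_bed(clusters: Sequence, path: PathLike) -> None:
    """Write called clusters as BED6.

    Name is ``cluster_<rank>``, score is the unique-piRNA count, strand is
    the dominant strand for strand-biased clusters and ``.`` otherwise.
    """
    with open(path, "wt") as fh:
        for c in clusters:
            strand = c.dominant_strand if c.bias_class != "unbiased" else "."
            if strand not in ("+", "-"):
                strand = "."
            fh.write(
                f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"cluster_{c.rank}\t{c.n_unique_pirnas}\t{strand}\n"
            )


def read_clusters_bed(
    path: PathLike,
) -> list[tuple[GenomicInterval, str, int]]:
    """Read a clusters BED back as (interval-with-strand, name, count) rows."""
    out = []
    with _opener(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected BED6")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
            out.append((iv, fields[3], int(fields[4])))
    return out
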