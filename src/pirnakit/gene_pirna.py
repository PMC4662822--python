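"""Genic piRNA quantification: RPM, sense and 3'-UTR fractions, TE filtering.

Reads are matched exactly (zero mismatches, full length) against the
spliced transcript sequence — the mature mRNA, i.e. the reverse complement
of the concatenated exons for minus-strand transcripts — so that piRNAs
derived from post-splicing RNA, including exon-junction reads, are
captured.  Abundance is normalized as RPM, reads per million genome-mapping
piRNAs.  Transcripts whose piRNAs are substantially shared with TE
consensus sequences are flagged, and dual-mapping reads are removed from
all genic statistics.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import SmallRNARead, TranscriptModel, revcomp

__all__ = [
    "TranscriptAlignment",
    "GenePiRNAProfile",
    "LengthProfile",
    "rpm",
    "rpm_group",
    "spliced_sequence",
    "utr3_transcript_range",
    "map_to_transcripts",
    "filter_genes_by_rpm",
    "te_contamination_filter",
    "utr3_fraction",
    "length_profile",
    "build_profiles",
    "collapse_to_genes",
]


@dataclass(frozen=True)
class TranscriptAlignment:
    """An exact placement of a read on a spliced transcript.

    ``start``/``end`` are 0-based half-open coordinates on the mature
    transcript (position 0 = the transcript's 5' end).  ``junction`` marks
    reads whose genomic projection spans more than one exon.
    """

    read_id: str
    transcript_id: str
    start: int
    end: int
    orientation: str  # sense | antisense relative to the transcript
    junction: bool = False


@dataclass
class GenePiRNAProfile:
    gene_id: str
    transcript_id: str
    n_reads: int                     # summed multiplicity of mapped reads
    rpm_unique: float
    sense_fraction: float
    utr3_fraction: Optional[float]   # None when the transcript has no 3'-UTR
    te_matching_rpm: float
    rpm_group: str
    length_histogram: dict[int, int] = field(default_factory=dict)


@dataclass
class LengthProfile:
    histogram: dict[int, int]
    sirna21: float        # fraction of mass at 21 nt
    pirna24_29: float     # fraction of mass at 24-29 nt


def rpm(count: float, total_genome_mappers: int) -> float:
    """Reads per million genome-mapping piRNAs."""
    if total_genome_mappers <= 0:
        raise ValueError("total_genome_mappers must be positive")
    return count / total_genome_mappers * 1e6


def rpm_group(rpm_value: float) -> str:
    """Bin an RPM into the reporting groups 5-10 / 10-50 / >50.

    Boundaries are half-open upward: [5,10) -> g5_10, [10,50) -> g10_50,
    [50,inf) -> g50plus, below 5 -> below.
    """
    if rpm_value >= 50:
        return "g50plus"
    if rpm_value >= 10:
        return "g10_50"
    if rpm_value >= 5:
        return "g5_10"
    return "below"


def spliced_sequence(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Mature transcript sequence: spliced exons, strand-corrected."""
    chrom = transcript.chrom
    if chrom not in genome:
        raise ValueError(f"{transcript.transcript_id}: chromosome {chrom!r} missing")
    seq = genome[chrom]
    parts = []
    for e in transcript.exons:
        if e.end > len(seq):
            raise ValueError(
                f"{transcript.transcript_id}: exon [{e.start},{e.end}) outside "
                f"{chrom} (length {len(seq)})"
            )
        parts.append(seq[e.start : e.end])
    concat = "".join(parts)
    return revcomp(concat) if transcript.strand == "-" else concat


def _exon_concat_offsets(transcript: TranscriptModel) -> list[int]:
    """Cumulative concatenated-exon start offsets (genomic exon order)."""
    offsets = [0]
    for e in transcript.exons:
        offsets.append(offsets[-1] + len(e))
    return offsets


def _genomic_to_concat(transcript: TranscriptModel, pos: int) -> int:
    offsets = _exon_concat_offsets(transcript)
    for i, e in enumerate(transcript.exons):
        if e.start <= pos < e.end:
            return offsets[i] + (pos - e.start)
    raise ValueError(
        f"{transcript.transcript_id}: genomic position {pos} not exonic"
    )


def utr3_transcript_range(transcript: TranscriptModel) -> Optional[tuple[int, int]]:
    """The 3'-UTR as a [start, end) range in mature-transcript coordinates."""
    if transcript.utr3 is None:
        return None
    c0 = _genomic_to_concat(transcript, transcript.utr3.start)
    c1 = _genomic_to_concat(transcript, transcript.utr3.end - 1) + 1
    if transcript.strand == "+":
        return c0, c1
    total = transcript.spliced_length()
    return total - c1, total - c0


def _is_junction(transcript: TranscriptModel, t0: int, t1: int) -> bool:
    """Does a mature-coordinate interval project across an exon boundary?"""
    total = transcript.spliced_length()
    if transcript.strand == "+":
        c0, c1 = t0, t1
    else:
        c0, c1 = total - t1, total - t0
    boundaries = _exon_concat_offsets(transcript)[1:-1]
    lo = bisect.bisect_right(boundaries, c0)
    hi = bisect.bisect_left(boundaries, c1)
    return hi > lo


def map_to_transcripts(
    reads: Sequence[SmallRNARead],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> dict[str, list[TranscriptAlignment]]:
    """Exact full-length placements of reads on spliced transcripts.

    Sense means the read equals a substring of the mature transcript;
    antisense means its reverse complement does.  Per read and transcript
    one placement is kept (sense preferred, then leftmost).  A read may
    align to several transcripts.
    """
    out: dict[str, list[TranscriptAlignment]] = {}
    for tx in transcripts:
        mature = spliced_sequence(tx, genome)
        alns: list[TranscriptAlignment] = []
        for read in reads:
            pos = mature.find(read.sequence)
            if pos >= 0:
                orientation = "sense"
            else:
                pos = mature.find(revcomp(read.sequence))
                if pos < 0:
                    continue
                orientation = "antisense"
            end = pos + len(read.sequence)
            alns.append(
                TranscriptAlignment(
                    read_id=read.id,
                    transcript_id=tx.transcript_id,
                    start=pos,
                    end=end,
                    orientation=orientation,
                    junction=_is_junction(tx, pos, end),
                )
            )
        out[tx.transcript_id] = alns
    return out


def utr3_fraction(
    alignments: Sequence[TranscriptAlignment],
    transcript: TranscriptModel,
    read_counts: Optional[Mapping[str, int]] = None,
) -> Optional[float]:
    """Fraction of a transcript's piRNAs lying entirely inside its 3'-UTR.

    Boundary-straddling reads count as outside.  Returns None when the
    transcript has no annotated 3'-UTR or no reads map.
    """
    utr = utr3_transcript_range(transcript)
    if utr is None:
        return None
    u0, u1 = utr
    total = inside = 0
    for a in alignments:
        w = read_counts.get(a.read_id, 1) if read_counts is not None else 1
        total += w
        if u0 <= a.start and a.end <= u1:
            inside += w
    if total == 0:
        return None
    return inside / total


def filter_genes_by_rpm(
    profiles: Sequence[GenePiRNAProfile], min_rpm: float = 0.5
) -> list[GenePiRNAProfile]:
    """Keep profiles with strictly more than ``min_rpm`` unique-piRNA RPM."""
    return [p for p in profiles if p.rpm_unique > min_rpm]


def te_contamination_filter(
    tx_alignments: Mapping[str, Sequence[TranscriptAlignment]],
    reads: Mapping[str, SmallRNARead],
    te_hit_ids: set[str],
    total_genome_mappers: int,
    min_te_rpm: float = 0.5,
) -> tuple[set[str], dict[str, list[TranscriptAlignment]]]:
    """Flag TE-contaminated transcripts and drop dual-mapping reads.

    A transcript is flagged when the RPM of its reads that are also TE
    consensus hits exceeds ``min_te_rpm``.  Independently of flagging,
    every read mapping to both a transcript and a TE is removed from the
    cleaned alignment sets used by downstream genic statistics.
    """
    flagged: set[str] = set()
    cleaned: dict[str, list[TranscriptAlignment]] = {}
    for tid, alns in tx_alignments.items():
        te_count = sum(
            reads[a.read_id].count
            for a in alns
            if a.read_id in te_hit_ids and a.read_id in reads
        )
        if rpm(te_count, total_genome_mappers) > min_te_rpm:
            flagged.add(tid)
        cleaned[tid] = [a for a in alns if a.read_id not in te_hit_ids]
    return flagged, cleaned


def length_profile(
    reads: Iterable[SmallRNARead], weighted: bool = True
) -> LengthProfile:
    """Read-length histogram with the 21-nt siRNA and 24-29-nt piRNA mass."""
    hist: dict[int, int] = defaultdict(int)
    for r in reads:
        hist[len(r.sequence)] += r.count if weighted else 1
    total = sum(hist.values())
    sirna21 = hist.get(21, 0) / total if total else 0.0
    pirna = sum(v for k, v in hist.items() if 24 <= k <= 29)
    return LengthProfile(
        histogram=dict(sorted(hist.items())),
        sirna21=sirna21,
        pirna24_29=pirna / total if total else 0.0,
    )


def build_profiles(
    transcripts: Sequence[TranscriptModel],
    tx_alignments: Mapping[str, Sequence[TranscriptAlignment]],
    reads: Mapping[str, SmallRNARead],
    te_hit_ids: set[str],
    total_genome_mappers: int,
) -> list[GenePiRNAProfile]:
    """Assemble per-transcript piRNA profiles from mapped alignments.

    Sense and 3'-UTR fractions and RPM are multiplicity-weighted; the
    caller supplies genome-unique reads so ``rpm_unique`` is the
    unique-mapper RPM.
    """
    profiles = []
    for tx in transcripts:
        alns = list(tx_alignments.get(tx.transcript_id, ()))
        alns = [a for a in alns if a.read_id in reads]
        n = sum(reads[a.read_id].count for a in alns)
        sense = sum(
            reads[a.read_id].count for a in alns if a.orientation == "sense"
        )
        te_count = sum(
            reads[a.read_id].count for a in alns if a.read_id in te_hit_ids
        )
        value = rpm(n, total_genome_mappers)
        mapped_reads = [reads[a.read_id] for a in alns]
        profiles.append(
            GenePiRNAProfile(
                gene_id=tx.gene_id,
                transcript_id=tx.transcript_id,
                n_reads=n,
                rpm_unique=value,
                sense_fraction=sense / n if n else 0.0,
                utr3_fraction=utr3_fraction(alns, tx, {r.id: r.count for r in mapped_reads}),
                te_matching_rpm=rpm(te_count, total_genome_mappers),
                rpm_group=rpm_group(value),
                length_histogram=length_profile(mapped_reads).histogram,
            )
        )
    return profiles


def collapse_to_genes(
    profiles: Sequence[GenePiRNAProfile],
) -> list[GenePiRNAProfile]:
    """One profile per gene: the transcript with the highest unique RPM.

    Ties are broken by transcript id for determinism.
    """
    best: dict[str, GenePiRNAProfile] = {}
    for p in profiles:
        cur = best.get(p.gene_id)
        if (
            cur is None
            or p.rpm_unique > cur.rpm_unique
            or (p.rpm_unique == cur.rpm_unique and p.transcript_id < cur.transcript_id)
        ):
            best[p.gene_id] = p
    return sorted(best.values(), key=lambda p: p.gene_id)
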