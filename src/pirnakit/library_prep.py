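"""Library strata, size selection, and read-category annotation.

Small-RNA libraries are analyzed in three strata:

* **NCNU** (non-collapsed, non-unique): every genome-mapping read with its
  full multiplicity, multi-mappers kept — used for TE attribution.
* **NCU** (non-collapsed, unique): genome-unique mappers with duplicates
  kept — used for genic piRNA quantification.
* **CU** (collapsed, unique): distinct genome-unique sequences, one
  occurrence each — used for cluster calling.

The module also provides an exact-match read mapper for the small synthetic
genomes the pipeline is tested on; real-data alignments are supplied as BED.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .io_formats import (
    AlignmentRecord,
    GenomicInterval,
    SmallRNARead,
    revcomp,
)

__all__ = [
    "LibraryStratum",
    "UniquenessResult",
    "DEFAULT_PRECEDENCE",
    "STRUCTURAL_CATEGORIES",
    "size_filter",
    "collapse",
    "classify_uniqueness",
    "map_reads_exact",
    "annotate_reads",
    "bona_fide_filter",
    "build_strata",
]

STRUCTURAL_CATEGORIES = ("miRNA", "rRNA", "tRNA", "snRNA")
DEFAULT_PRECEDENCE = ("miRNA", "rRNA", "tRNA", "snRNA", "TE", "gene")


@dataclass
class LibraryStratum:
    label: str  # NCNU | NCU | CU
    reads: list[SmallRNARead]
    alignments: list[AlignmentRecord]
    total_reads: int
    total_genome_mappers: int


@dataclass
class UniquenessResult:
    n_hits: dict[str, int]          # read id -> number of genomic placements
    unique_ids: set[str]            # exactly one placement
    unmapped_ids: set[str]          # zero placements (only if reads given)


def size_filter(
    reads: Iterable[SmallRNARead], min_len: int, max_len: int
) -> list[SmallRNARead]:
    """Keep reads whose length is within [min_len, max_len], counts intact."""
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid size range [{min_len}, {max_len}]")
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse(
    reads: Iterable[SmallRNARead],
) -> tuple[list[SmallRNARead], dict[str, int]]:
    """Reduce duplicate sequences to one occurrence each.

    Returns the collapsed reads (count 1, ordered lexicographically by
    sequence, id = lexicographically first id among the duplicates) and a
    parallel {sequence: summed original multiplicity} map.
    """
    totals: dict[str, int] = defaultdict(int)
    ids: dict[str, str] = {}
    for r in reads:
        totals[r.sequence] += r.count
        if r.sequence not in ids or r.id < ids[r.sequence]:
            ids[r.sequence] = r.id
    collapsed = [
        SmallRNARead(id=ids[seq], sequence=seq, count=1)
        for seq in sorted(totals)
    ]
    return collapsed, dict(totals)


def classify_uniqueness(
    alignments: Iterable[AlignmentRecord],
    reads: Optional[Iterable[SmallRNARead]] = None,
) -> UniquenessResult:
    """Count genomic placements per read and split unique from multi-mappers.

    A read's placement count is the number of alignment records carrying its
    id (or, if larger, the ``n_genome_hits`` those records declare, so that
    pre-filtered BED files that only list one placement per multi-mapper are
    still classified correctly).  When ``reads`` is given, reads with no
    alignment at all are tallied as unmapped.
    """
    seen: dict[str, int] = defaultdict(int)
    declared: dict[str, int] = {}
    for a in alignments:
        seen[a.read_id] += 1
        declared[a.read_id] = max(declared.get(a.read_id, 1), a.n_genome_hits)
    n_hits = {rid: max(cnt, declared[rid]) for rid, cnt in seen.items()}
    unique = {rid for rid, n in n_hits.items() if n == 1}
    unmapped: set[str] = set()
    if reads is not None:
        unmapped = {r.id for r in reads if r.id not in n_hits}
    return UniquenessResult(n_hits=n_hits, unique_ids=unique, unmapped_ids=unmapped)


def _kmer_index(genome: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in genome.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].append((chrom, i))
    return dict(index)


def map_reads_exact(
    reads: Sequence[SmallRNARead],
    genome: Mapping[str, str],
    seed_k: int = 16,
) -> list[AlignmentRecord]:
    """Find every exact full-length genomic placement of each read.

    A minus-strand placement means the reverse complement of the read
    occurs at the reported interval.  Placements are seeded on the read's
    first ``seed_k``-mer against a genome k-mer index and verified by full
    string comparison, so runtime is linear in genome size plus hits.
    Intended for the small synthetic genomes used in testing; real-data
    alignments enter the pipeline as BED.
    """
    index = _kmer_index(genome, seed_k)
    out: list[AlignmentRecord] = []
    placements_cache: dict[str, list[tuple[str, int, str]]] = {}
    for read in reads:
        seq = read.sequence
        if len(seq) < seed_k:
            raise ValueError(
                f"read {read.id}: length {len(seq)} below seed size {seed_k}"
            )
        if seq not in placements_cache:
            hits: list[tuple[str, int, str]] = []
            for strand, query in (("+", seq), ("-", revcomp(seq))):
                for chrom, pos in index.get(query[:seed_k], ()):  # seed
                    if genome[chrom][pos : pos + len(query)] == query:
                        hits.append((chrom, pos, strand))
            hits.sort()
            placements_cache[seq] = hits
        hits = placements_cache[seq]
        for chrom, pos, strand in hits:
            out.append(
                AlignmentRecord(
                    read_id=read.id,
                    interval=GenomicInterval(chrom, pos, pos + len(seq), strand),
                    n_genome_hits=len(hits),
                )
            )
    return out


def _matches_track(seq: str, references: Sequence[str]) -> bool:
    rc = revcomp(seq)
    return any(seq in ref or rc in ref for ref in references)


def annotate_reads(
    reads: Sequence[SmallRNARead],
    annotation_tracks: Mapping[str, Sequence[str]],
    te_attributor: Optional[Callable[[Sequence[SmallRNARead]], set[str]]] = None,
    transcript_seqs: Optional[Sequence[str]] = None,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> dict[str, str]:
    """Assign each read one category under a configurable precedence.

    Structural-RNA tracks (miRNA/rRNA/tRNA/snRNA reference sequences) match
    at zero mismatches (exact substring, either orientation).  ``TE`` is
    delegated to ``te_attributor`` (typically a closure over
    ``te_attribution.consensus_map`` with its 3-mismatch allowance) which
    returns the set of TE-matching read ids.  ``gene`` matches exactly
    against spliced transcript sequences.  Reads matching nothing are
    ``unannotated``.
    """
    te_hit_ids: set[str] = set()
    if te_attributor is not None and "TE" in precedence:
        te_hit_ids = te_attributor(reads)

    categories: dict[str, str] = {}
    for read in reads:
        label = "unannotated"
        for cat in precedence:
            if cat == "TE":
                if read.id in te_hit_ids:
                    label = "TE"
                    break
            elif cat == "gene":
                if transcript_seqs and _matches_track(read.sequence, transcript_seqs):
                    label = "gene"
                    break
            else:
                refs = annotation_tracks.get(cat, ())
                if refs and _matches_track(read.sequence, refs):
                    label = cat
                    break
        categories[read.id] = label
    return categories


def bona_fide_filter(
    reads: Iterable[SmallRNARead], annotations: Mapping[str, str]
) -> list[SmallRNARead]:
    """Drop structural-RNA reads (miRNA, rRNA, tRNA, snRNA); keep the rest."""
    return [r for r in reads if annotations.get(r.id) not in STRUCTURAL_CATEGORIES]


def build_strata(
    reads: Sequence[SmallRNARead],
    alignments: Sequence[AlignmentRecord],
) -> dict[str, LibraryStratum]:
    """Build the NCNU / NCU / CU strata from reads and their placements.

    Only genome-mapping reads enter any stratum; ``total_genome_mappers``
    (the RPM denominator) is the summed multiplicity of NCNU reads.
    """
    uniq = classify_uniqueness(alignments, reads)
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        by_read[a.read_id].append(a)

    mapped = [r for r in reads if r.id in uniq.n_hits]
    ncnu_alns = [a for r in mapped for a in by_read[r.id]]
    total_mappers = sum(r.count for r in mapped)

    ncu_reads = [r for r in mapped if r.id in uniq.unique_ids]
    ncu_alns = [a for r in ncu_reads for a in by_read[r.id]]
    ncu_total = sum(r.count for r in ncu_reads)

    cu_reads, _orig = collapse(ncu_reads)
    # a collapsed read keeps the single placement of (any of) its duplicates;
    # genome-unique duplicates share one locus by definition
    first_aln = {r.id: by_read[r.id][0] for r in ncu_reads}
    seq_to_aln: dict[str, AlignmentRecord] = {}
    for r in ncu_reads:
        if r.sequence not in seq_to_aln:
            seq_to_aln[r.sequence] = first_aln[r.id]
    cu_alns = [
        AlignmentRecord(
            read_id=r.id,
            interval=seq_to_aln[r.sequence].interval,
            n_genome_hits=1,
        )
        for r in cu_reads
    ]

    return {
        "NCNU": LibraryStratum("NCNU", mapped, ncnu_alns, total_mappers, total_mappers),
        "NCU": LibraryStratum("NCU", ncu_reads, ncu_alns, ncu_total, total_mappers),
        "CU": LibraryStratum("CU", cu_reads, cu_alns, len(cu_reads), total_mappers),
    }
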