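"""Attribution of piRNAs to transposable elements by two methods.

*Consensus* method: a read (or its reverse complement) is placed end-to-end,
ungapped, inside a TE consensus sequence at Hamming distance up to three —
tolerant of TE copies that have diverged from their family consensus.

*Overlap* method: a read must occur exactly (zero mismatches, full length)
inside a single repeat-masked genomic interval, inheriting that copy's TE
identity — tolerant of poorly annotated families, intolerant of divergence
from the genomic copy.

Each method reports at most one hit per read, with deterministic
tie-breaking (fewest mismatches, then TE name, then offset for consensus;
first masked interval by genomic position for overlap).  Orientation is
*sense* when the read runs in the same direction as the TE itself.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import overlap_with_union, union_length
from .io_formats import (
    GenomicInterval,
    MaskedInterval,
    SmallRNARead,
    TEConsensus,
    revcomp,
)

__all__ = [
    "TEHit",
    "consensus_map",
    "overlap_map",
    "aggregate_by_te",
    "antisense_fraction",
    "genome_te_landscape",
]


@dataclass(frozen=True)
class TEHit:
    read_id: str
    te_name: str
    te_class: str
    te_family: str
    orientation: str  # sense | antisense, relative to the TE's orientation
    n_mismatches: int
    method: str  # consensus | overlap


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _ConsensusIndex:
    """Sliding-window views over one consensus, cached per read length."""

    def __init__(self, te: TEConsensus):
        self.te = te
        self._arr = _encode(te.sequence)
        self._views: dict[int, np.ndarray] = {}

    def windows(self, read_len: int) -> Optional[np.ndarray]:
        if read_len > len(self._arr):
            return None
        if read_len not in self._views:
            self._views[read_len] = np.lib.stride_tricks.sliding_window_view(
                self._arr, read_len
            )
        return self._views[read_len]


def consensus_map(
    reads: Sequence[SmallRNARead],
    te_library: Sequence[TEConsensus],
    max_mismatches: int = 3,
    chunk: int = 256,
) -> list[TEHit]:
    """Best ungapped end-to-end placement of each read in the TE library.

    A hit is a full-length placement of the read or its reverse complement
    within a consensus at Hamming distance <= ``max_mismatches``.  Per read
    the single best hit is reported: fewest mismatches, ties broken by TE
    name, then offset, then sense before antisense.
    """
    if not te_library:
        raise ValueError("empty TE library")
    indexes = [_ConsensusIndex(te) for te in sorted(te_library, key=lambda t: t.name)]

    # distinct sequences only; reads sharing a sequence share the hit
    seq_reads: dict[str, list[str]] = defaultdict(list)
    for r in reads:
        seq_reads[r.sequence].append(r.id)
    by_len: dict[int, list[str]] = defaultdict(list)
    for seq in seq_reads:
        by_len[len(seq)].append(seq)

    # best[seq] = (mm, te_name, offset, orient_rank)
    best: dict[str, tuple[int, str, int, int]] = {}
    for read_len, seqs in by_len.items():
        seqs.sort()
        fw = np.stack([_encode(s) for s in seqs])
        rc = np.stack([_encode(revcomp(s)) for s in seqs])
        for idx in indexes:
            windows = idx.windows(read_len)
            if windows is None:
                continue
            for orient_rank, queries in ((0, fw), (1, rc)):
                for lo in range(0, len(seqs), chunk):
                    hi = min(lo + chunk, len(seqs))
                    # (chunk, offsets) mismatch counts
                    mm = (
                        queries[lo:hi, None, :] != windows[None, :, :]
                    ).sum(axis=2)
                    best_off = mm.argmin(axis=1)
                    best_mm = mm[np.arange(hi - lo), best_off]
                    for j in np.flatnonzero(best_mm <= max_mismatches):
                        seq = seqs[lo + j]
                        cand = (
                            int(best_mm[j]),
                            idx.te.name,
                            int(best_off[j]),
                            orient_rank,
                        )
                        if seq not in best or cand < best[seq]:
                            best[seq] = cand

    te_by_name = {te.name: te for te in te_library}
    hits = []
    for seq, (mm, te_name, _offset, orient_rank) in best.items():
        te = te_by_name[te_name]
        for read_id in seq_reads[seq]:
            hits.append(
                TEHit(
                    read_id=read_id,
                    te_name=te.name,
                    te_class=te.te_class,
                    te_family=te.te_family,
                    orientation="sense" if orient_rank == 0 else "antisense",
                    n_mismatches=mm,
                    method="consensus",
                )
            )
    hits.sort(key=lambda h: h.read_id)
    return hits


def overlap_map(
    reads: Sequence[SmallRNARead],
    masked_intervals: Sequence[MaskedInterval],
    genome: Mapping[str, str],
) -> list[TEHit]:
    """Exact full-length containment of each read in a masked TE copy.

    A read hits a masked interval when the read or its reverse complement
    occurs verbatim inside the interval's genomic sequence; reads straddling
    an interval boundary do not hit.  One hit per read, taken from the first
    matching interval in (chrom, start) order; orientation is sense when the
    read's genomic strand equals the masked copy's strand.
    """
    extracted: list[tuple[MaskedInterval, str]] = []
    for m in sorted(
        masked_intervals, key=lambda m: (m.interval.chrom, m.interval.start)
    ):
        chrom = m.interval.chrom
        if chrom not in genome or m.interval.end > len(genome[chrom]):
            raise ValueError(
                f"masked interval {chrom}:{m.interval.start}-{m.interval.end} "
                "outside genome bounds"
            )
        extracted.append((m, genome[chrom][m.interval.start : m.interval.end]))

    seq_hit: dict[str, Optional[tuple[MaskedInterval, str]]] = {}
    hits = []
    for r in sorted(reads, key=lambda r: r.id):
        if r.sequence not in seq_hit:
            found = None
            rc = revcomp(r.sequence)
            for m, copy_seq in extracted:
                if r.sequence in copy_seq:
                    genomic_strand = "+"
                elif rc in copy_seq:
                    genomic_strand = "-"
                else:
                    continue
                found = (m, genomic_strand)
                break
            seq_hit[r.sequence] = found
        found = seq_hit[r.sequence]
        if found is None:
            continue
        m, genomic_strand = found
        copy_strand = m.interval.strand if m.interval.strand in "+-" else "+"
        hits.append(
            TEHit(
                read_id=r.id,
                te_name=m.te_name,
                te_class=m.te_class,
                te_family=m.te_family,
                orientation="sense" if genomic_strand == copy_strand else "antisense",
                n_mismatches=0,
                method="overlap",
            )
        )
    return hits


def aggregate_by_te(
    hits: Sequence[TEHit],
    read_counts: Optional[Mapping[str, int]] = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Fractions of hit reads per TE class and per TE family.

    With ``read_counts`` (read id -> multiplicity) the tally is weighted by
    library multiplicity; otherwise each hit read counts once.  Fractions
    sum to 1 at each level; empty input yields empty tables.
    """
    class_tally: dict[str, float] = defaultdict(float)
    family_tally: dict[str, float] = defaultdict(float)
    total = 0.0
    for h in hits:
        w = read_counts.get(h.read_id, 1) if read_counts is not None else 1
        class_tally[h.te_class] += w
        family_tally[h.te_family or h.te_name] += w
        total += w
    if total == 0:
        return {}, {}
    return (
        {k: v / total for k, v in class_tally.items()},
        {k: v / total for k, v in family_tally.items()},
    )


def antisense_fraction(
    hits: Sequence[TEHit],
    read_counts: Optional[Mapping[str, int]] = None,
) -> float:
    """Fraction of TE-derived piRNAs that oppose their TE's orientation."""
    if not hits:
        raise ValueError("antisense fraction of an empty hit list is undefined")
    total = anti = 0.0
    for h in hits:
        w = read_counts.get(h.read_id, 1) if read_counts is not None else 1
        total += w
        if h.orientation == "antisense":
            anti += w
    return anti / total


def genome_te_landscape(
    masked_intervals: Sequence[MaskedInterval],
    chrom_lengths: Mapping[str, int],
    domains: Optional[Sequence[tuple[GenomicInterval, str]]] = None,
) -> dict:
    """Genomic TE coverage overall, per class/family, and per chromatin domain.

    All coverages are bp-union based (overlapping copies counted once) and
    normalized by total genome length, or by domain length for the
    per-domain table.
    """
    genome_bp = sum(chrom_lengths.values())
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")

    def spans_by_chrom(items: Iterable[MaskedInterval]) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for m in items:
            out[m.interval.chrom].append((m.interval.start, m.interval.end))
        return out

    def union_bp(items: Iterable[MaskedInterval]) -> int:
        return sum(union_length(s) for s in spans_by_chrom(items).values())

    by_class: dict[str, list[MaskedInterval]] = defaultdict(list)
    by_family: dict[str, list[MaskedInterval]] = defaultdict(list)
    for m in masked_intervals:
        by_class[m.te_class].append(m)
        by_family[m.te_family or m.te_name].append(m)

    result = {
        "total": union_bp(masked_intervals) / genome_bp,
        "class": {k: union_bp(v) / genome_bp for k, v in by_class.items()},
        "family": {k: union_bp(v) / genome_bp for k, v in by_family.items()},
    }

    if domains is not None:
        all_spans = spans_by_chrom(masked_intervals)
        domain_cov: dict[str, list[int]] = defaultdict(lambda: [0, 0])
        for iv, label in domains:
            covered = overlap_with_union(
                (iv.start, iv.end), all_spans.get(iv.chrom, [])
            )
            domain_cov[label][0] += covered
            domain_cov[label][1] += len(iv)
        result["domain"] = {
            label: cov / size for label, (cov, size) in domain_cov.items() if size
        }
    return result
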