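"""Ping-pong and positional nucleotide signatures.

The ping-pong amplification cycle leaves two footprints in a piRNA
library: complementary reads whose 5' ends overlap by exactly 10 nt, and
positional base biases — uridine at position 1 of primary (mostly
antisense) piRNAs, adenine at position 10 of secondary (sense) piRNAs,
the latter being the complement of the former across the 10-nt overlap.

The 5'-5' overlap between a plus-strand 5' end at ``p`` and a minus-strand
5' end at ``q`` (the minus read's rightmost base) is ``k = q - p + 1``;
read lengths play no further role.  The histogram over ``k`` in
``[1, k_max]`` peaks at 10 in a ping-pong-active library; ``z10`` scores
that bin against the remaining offsets as background.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import AlignmentRecord, SmallRNARead
from .te_attribution import TEHit

__all__ = [
    "PingPongProfile",
    "PositionalComposition",
    "base_fraction_at",
    "te_signature_table",
    "ping_pong_histogram",
    "overlap_composition",
]


@dataclass
class PingPongProfile:
    overlap_counts: dict[int, float]      # offset k -> weight
    z10: Optional[float]                  # z-score of k=10 vs other offsets
    n_pairs: int                          # opposite-strand 5'-end pairs seen
    pairs_at_10: list[tuple[str, str]] = field(default_factory=list)
    weighting: str = "reads"

    @property
    def modal_offset(self) -> Optional[int]:
        nonzero = {k: v for k, v in self.overlap_counts.items() if v > 0}
        if not nonzero:
            return None
        return min(nonzero, key=lambda k: (-nonzero[k], k))


@dataclass
class PositionalComposition:
    """Per-position base frequencies (positions 1..10 from each 5' end)."""

    matrix: dict[int, dict[str, float]]
    n_reads: int


def base_fraction_at(
    reads: Sequence[SmallRNARead],
    position: int,
    base: str,
    weighted: bool = False,
) -> float:
    """Fraction of reads carrying ``base`` at a 1-based position.

    ``U`` and ``T`` are interchangeable.  Reads shorter than ``position``
    leave the denominator; an empty denominator is an error.
    """
    if position < 1:
        raise ValueError("position is 1-based and must be >= 1")
    want = base.upper().replace("U", "T")
    total = hit = 0
    for r in reads:
        if len(r.sequence) < position:
            continue
        w = r.count if weighted else 1
        total += w
        if r.sequence[position - 1] == want:
            hit += w
    if total == 0:
        raise ValueError(f"no read reaches position {position}")
    return hit / total


def te_signature_table(
    te_hits: Sequence[TEHit],
    reads: Mapping[str, SmallRNARead],
    weighted: bool = False,
) -> dict[str, dict[str, float]]:
    """1U and 10A fractions of the sense and antisense TE-hit read subsets.

    Returns ``{orientation: {"1U": f, "10A": f}}``; an orientation with no
    hits is absent, and a cell whose denominator is empty is absent.
    """
    subsets: dict[str, list[SmallRNARead]] = defaultdict(list)
    for h in te_hits:
        if h.read_id in reads:
            subsets[h.orientation].append(reads[h.read_id])
    table: dict[str, dict[str, float]] = {}
    for orientation, subset in subsets.items():
        cells: dict[str, float] = {}
        for label, (pos, base) in (("1U", (1, "T")), ("10A", (10, "A"))):
            try:
                cells[label] = base_fraction_at(subset, pos, base, weighted)
            except ValueError:
                continue
        if cells:
            table[orientation] = cells
    return table


def ping_pong_histogram(
    alignments: Sequence[AlignmentRecord],
    read_counts: Optional[Mapping[str, int]] = None,
    k_max: int = 30,
    weighting: str = "reads",
) -> PingPongProfile:
    """Histogram of 5'-5' overlaps between opposite-strand reads.

    ``weighting='pairs'`` accumulates, per offset, the product of read
    multiplicities over all plus/minus 5'-end pairs; ``'reads'`` counts the
    distinct reads having at least one opposite-strand partner at that
    offset.  ``z10`` compares bin 10 with the mean and standard deviation
    of the other offsets; it is undefined (None) when those have no spread.
    """
    if weighting not in ("reads", "pairs"):
        raise ValueError(f"unknown weighting {weighting!r}")

    def count_of(read_id: str) -> int:
        return read_counts.get(read_id, 1) if read_counts is not None else 1

    plus_at: dict[tuple[str, int], list[str]] = defaultdict(list)
    minus_at: dict[tuple[str, int], list[str]] = defaultdict(list)
    for a in alignments:
        key = (a.interval.chrom, a.five_prime)
        (plus_at if a.strand == "+" else minus_at)[key].append(a.read_id)

    counts: dict[int, float] = {k: 0.0 for k in range(1, k_max + 1)}
    reads_at_k: dict[int, set[str]] = defaultdict(set)
    pairs_at_10: list[tuple[str, str]] = []
    n_pairs = 0
    for (chrom, q), minus_ids in minus_at.items():
        for k in range(1, k_max + 1):
            plus_ids = plus_at.get((chrom, q - k + 1))
            if not plus_ids:
                continue
            n_pairs += len(plus_ids) * len(minus_ids)
            if weighting == "pairs":
                counts[k] += sum(count_of(i) for i in plus_ids) * sum(
                    count_of(j) for j in minus_ids
                )
            else:
                reads_at_k[k].update(plus_ids)
                reads_at_k[k].update(minus_ids)
            if k == 10:
                pairs_at_10.extend(
                    (pid, mid) for pid in plus_ids for mid in minus_ids
                )
    if weighting == "reads":
        for k, ids in reads_at_k.items():
            counts[k] = float(len(ids))

    background = [counts[k] for k in counts if k != 10]
    z10: Optional[float] = None
    if len(background) >= 2:
        sd = stdev(background)
        if sd > 0:
            z10 = (counts[10] - mean(background)) / sd
    return PingPongProfile(
        overlap_counts=counts,
        z10=z10,
        n_pairs=n_pairs,
        pairs_at_10=pairs_at_10,
        weighting=weighting,
    )


def overlap_composition(
    pairs: Sequence[tuple[str, str]],
    reads: Mapping[str, SmallRNARead],
) -> PositionalComposition:
    """Base composition over the 10-nt overlap of ping-pong partners.

    Positions are numbered 1-10 from each partner read's own 5' end; both
    partners of every pair contribute.  Reads shorter than 10 nt are
    skipped.  Frequencies are reported over A/C/G/U.
    """
    tallies: dict[int, dict[str, int]] = {
        pos: {b: 0 for b in "ACGT"} for pos in range(1, 11)
    }
    n_reads = 0
    for pair in pairs:
        for read_id in pair:
            read = reads.get(read_id)
            if read is None or len(read.sequence) < 10:
                continue
            n_reads += 1
            for pos in range(1, 11):
                base = read.sequence[pos - 1]
                if base in tallies[pos]:
                    tallies[pos][base] += 1
    matrix: dict[int, dict[str, float]] = {}
    if n_reads:
        for pos, row in tallies.items():
            total = sum(row.values())
            if total:
                matrix[pos] = {
                    ("U" if b == "T" else b): v / total for b, v in row.items()
                }
    return PositionalComposition(matrix=matrix, n_reads=n_reads)
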