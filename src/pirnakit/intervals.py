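"""Tiny interval-arithmetic helpers shared by cluster and TE accounting."""

from __future__ import annotations

from typing import Iterable

from intervaltree import IntervalTree


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching [start, end) spans into a sorted union."""
    tree = IntervalTree.from_tuples((s, e) for s, e in spans if e > s)
    tree.merge_overlaps(strict=False)  # strict=False also fuses touching spans
    return sorted((iv.begin, iv.end) for iv in tree)


def union_length(spans: Iterable[tuple[int, int]]) -> int:
    """Total bp covered by the union of [start, end) spans."""
    return sum(end - start for start, end in merge_intervals(spans))


def overlap_with_union(
    target: tuple[int, int], spans: Iterable[tuple[int, int]]
) -> int:
    """Bp of ``target`` covered by the union of ``spans``."""
    t0, t1 = target
    return sum(
        max(0, min(t1, e) - max(t0, s)) for s, e in merge_intervals(spans)
    )
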