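"""Interval merging and overlap queries (0-based, half-open everywhere)."""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

from intervaltree import IntervalTree


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or book-ended intervals into a sorted disjoint list.

    Book-ended pairs (``end == start``) are merged: consensus regions should
    not be split by zero-length gaps.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"interval start must be < end: ({s}, {e})")
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


class GenomeIntervalIndex:
    """Per-chromosome interval index with deterministic overlap queries.

    Members are arbitrary hashable payloads attached to ``(chrom, start, end)``.
    Queries return members sharing >= 1 base with the query, ordered by
    (start, end, insertion order).
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0

    def add(self, chrom: str, start: int, end: int, member: Hashable) -> None:
        if start >= end:
            raise ValueError(f"interval start must be < end: ({start}, {end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, (self._n, member))
        self._n += 1

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, int, int, Hashable]]) -> "GenomeIntervalIndex":
        idx = cls()
        for chrom, start, end, member in items:
            idx.add(chrom, start, end, member)
        return idx

    def overlap_query(self, chrom: str, start: int, end: int) -> list:
        """All members overlapping [start, end) on chrom; unknown chrom -> []."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: (iv.begin, iv.end, iv.data[0]))
        return [iv.data[1] for iv in hits]

    def overlaps_point(self, chrom: str, pos: int) -> list:
        return self.overlap_query(chrom, pos, pos + 1)

    def __len__(self) -> int:
        return self._n


def brute_force_overlap(
    intervals: Sequence[tuple[str, int, int, Hashable]], chrom: str, start: int, end: int
) -> list:
    """Reference all-pairs scan; oracle for GenomeIntervalIndex in tests."""
    hits = [
        (s, e, i, m)
        for i, (c, s, e, m) in enumerate(intervals)
        if c == chrom and s < end and start < e
    ]
    return [m for _, _, _, m in sorted(hits, key=lambda h: (h[0], h[1], h[2]))]
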