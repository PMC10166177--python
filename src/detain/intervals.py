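"""Small utilities on genomic intervals.

All intervals are 0-based, half-open ``(start, end)`` tuples on a single
reference sequence; callers are responsible for keeping chromosomes apart.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or adjacent intervals into a sorted disjoint set."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def covered_length(intervals: Iterable[Interval], start: int, end: int) -> int:
    """Number of bases of ``[start, end)`` covered by the interval union."""
    return sum(
        overlap_length((s, e), (start, end)) for s, e in merge_intervals(intervals)
    )


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def span(intervals: Sequence[Interval]) -> Interval:
    return min(s for s, _ in intervals), max(e for _, e in intervals)
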