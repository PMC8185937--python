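"""Arithmetic on 1-based closed intervals ``(start, end)``.

These helpers back call merging, blacklist subtraction and burden
computation; they deliberately stay coordinate-system agnostic (no
chromosome awareness — callers group by chromosome first).
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def validate_interval(iv: Interval) -> None:
    start, end = iv
    if end < start:
        raise ValueError(f"interval end {end} < start {start}")


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: overlapping intervals merged, sorted output.

    Adjacent-but-disjoint intervals (e.g. (1,5) and (6,9)) are kept separate;
    only intervals sharing at least one base are merged.
    """
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        validate_interval((start, end))
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def subtract_intervals(iv: Interval, cutters: Iterable[Interval]) -> list[Interval]:
    """Set-difference of one interval with a collection of intervals."""
    validate_interval(iv)
    remaining = [iv]
    for cut in merge_intervals(cutters):
        out: list[Interval] = []
        for start, end in remaining:
            if cut[1] < start or cut[0] > end:
                out.append((start, end))
                continue
            if cut[0] > start:
                out.append((start, cut[0] - 1))
            if cut[1] < end:
                out.append((cut[1] + 1, end))
        remaining = out
    return remaining


def total_length(intervals: Iterable[Interval]) -> int:
    """Summed closed-interval lengths; intervals assumed disjoint."""
    return sum(end - start + 1 for start, end in intervals)


def covered_length(intervals: Iterable[Interval]) -> int:
    """Number of distinct bases covered by a (possibly overlapping) set."""
    return total_length(merge_intervals(intervals))


def overlap_length(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def covers(intervals: Sequence[Interval], pos: int) -> bool:
    return any(start <= pos <= end for start, end in intervals)
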