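"""Interval arithmetic on 0-based half-open genomic intervals.

These primitives reproduce bedtools-style intersection semantics (an
overlap requires >= 1 shared base under half-open coordinates) with a
sweep-line implementation, plus gap-tolerant merging used by both the
DMR and siRNA-locus mergers.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np


def overlap_length(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def intersect(
    intervals_a: Sequence[tuple[int, int]],
    intervals_b: Sequence[tuple[int, int]],
) -> list[tuple[int, int, int]]:
    """All overlapping pairs between two interval sets on one chromosome.

    Parameters
    ----------
    intervals_a, intervals_b
        Sequences of ``(start, end)`` half-open intervals. Need not be
        sorted; sorting is done internally (indices reported refer to the
        input order).

    Returns
    -------
    list of ``(i, j, overlap_bp)`` with ``overlap_bp >= 1``, sorted by
    ``(i, j)``.
    """
    a = sorted(range(len(intervals_a)), key=lambda i: intervals_a[i][0])
    b = sorted(range(len(intervals_b)), key=lambda j: intervals_b[j][0])
    out: list[tuple[int, int, int]] = []
    start_j = 0
    for ia in a:
        a_start, a_end = intervals_a[ia]
        # advance past b-intervals that end before any later a can start
        while start_j < len(b) and intervals_b[b[start_j]][1] <= a_start:
            # safe to discard only if every later a starts at or after a_start,
            # which holds because a is sorted by start
            start_j += 1
        for jj in range(start_j, len(b)):
            jb = b[jj]
            b_start, b_end = intervals_b[jb]
            if b_start >= a_end:
                break
            ov = overlap_length(a_start, a_end, b_start, b_end)
            if ov >= 1:
                out.append((ia, jb, ov))
    out.sort()
    return out


def merge(
    intervals: Sequence[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int, list[int]]]:
    """Merge intervals whose gap is <= ``max_gap``.

    ``max_gap=0`` merges overlapping or exactly abutting intervals;
    ``max_gap=150`` additionally bridges gaps of up to 150 bp (inclusive).

    Returns a list of ``(start, end, member_indices)`` sorted by start,
    where member indices refer to the input order.
    """
    if len(intervals) == 0:
        return []
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i][0], intervals[i][1]))
    merged: list[tuple[int, int, list[int]]] = []
    cur_start, cur_end = intervals[order[0]]
    members = [order[0]]
    for i in order[1:]:
        s, e = intervals[i]
        if s - cur_end <= max_gap:
            cur_end = max(cur_end, e)
            members.append(i)
        else:
            merged.append((cur_start, cur_end, members))
            cur_start, cur_end, members = s, e, [i]
    merged.append((cur_start, cur_end, members))
    return merged


def assert_sorted(chroms: np.ndarray, starts: np.ndarray) -> None:
    """Raise ``ValueError`` unless rows are sorted by (chrom block, start)."""
    prev_chrom = None
    prev_start = -1
    seen = set()
    for c, s in zip(chroms, starts):
        if c != prev_chrom:
            if c in seen:
                raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
            seen.add(c)
            prev_chrom, prev_start = c, -1
        if s < prev_start:
            raise ValueError(f"positions not sorted on {c!r}: {s} after {prev_start}")
        prev_start = s
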