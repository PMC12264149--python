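"""Half-open genomic interval algebra on plain (start, end) tuples.

All coordinates are 0-based half-open. Functions accept any iterable of
(start, end) pairs and return sorted, merged lists.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or bookended intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    if not ivs:
        return []
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Set difference a \\ b, both merged first."""
    a = merge(a)
    b = merge(b)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    a = merge(a)
    b = merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlaps_any(start: int, end: int, merged: List[Interval]) -> bool:
    """True if [start, end) overlaps any interval of a merged, sorted list."""
    if not merged:
        return False
    starts = [s for s, _ in merged]
    i = bisect_right(starts, start) - 1
    if i >= 0 and merged[i][1] > start:
        return True
    i += 1
    return i < len(merged) and merged[i][0] < end


def overlap_length(start: int, end: int, merged: List[Interval]) -> int:
    n = 0
    for s, e in merged:
        if s >= end:
            break
        n += max(0, min(e, end) - max(s, start))
    return n
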