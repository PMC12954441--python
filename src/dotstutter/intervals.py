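"""Small helpers for 0-based half-open genomic intervals.

All coordinates in this package are 0-based half-open; converters at the
I/O boundary (GTF, RepeatMasker) are the only places other conventions
appear.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/touching-by-overlap merged.

    Touching intervals ((0,10),(10,20)) are NOT merged — half-open
    adjacency is not overlap.
    """
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval ({s},{e})")
        if out and s < out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def total_overlap(iv: Interval, merged: Sequence[Interval]) -> int:
    """Bases of ``iv`` covered by a *merged* (disjoint, sorted) interval set."""
    if not merged:
        return 0
    starts = [m[0] for m in merged]
    i = max(0, bisect_left(starts, iv[0]) - 1)
    covered = 0
    for j in range(i, len(merged)):
        if merged[j][0] >= iv[1]:
            break
        covered += overlap_len(iv, merged[j])
    return covered


def gaps_between(intervals: Sequence[Interval], min_len: int = 1) -> list[Interval]:
    """Maximal gaps between consecutive non-overlapping sorted intervals."""
    out = []
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("intervals overlap; merge first")
        if s2 - e1 >= min_len:
            out.append((e1, s2))
    return out
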