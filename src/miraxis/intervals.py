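"""Half-open interval algebra on a single sequence.

All intervals are 0-based half-open ``(start, end)`` tuples with
``start < end``. These helpers back exon merging and intron derivation;
they are deliberately free of any genomic-range container so the rest of
the package can stay in plain tuples.
"""
from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping or abutting intervals into a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            prev_s, prev_e = merged[-1]
            merged[-1] = (prev_s, max(prev_e, e))
        else:
            merged.append((s, e))
    return merged


def subtract_intervals(span: Interval, blocks: Sequence[Interval]) -> List[Interval]:
    """Return ``span`` minus the union of ``blocks``, clipped to ``span``."""
    start, end = span
    out: List[Interval] = []
    cursor = start
    for bs, be in merge_intervals(blocks):
        bs, be = max(bs, start), min(be, end)
        if be <= bs:
            continue
        if bs > cursor:
            out.append((cursor, bs))
        cursor = max(cursor, be)
    if cursor < end:
        out.append((cursor, end))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]
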