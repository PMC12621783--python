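"""Tiny 0-based half-open interval arithmetic used by QC and masking."""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge(intervals: Iterable[Interval], join_adjacent: bool = True) -> list[Interval]:
    """Union of intervals, sorted and non-overlapping."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (join_adjacent and s == out[-1][1])):
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract(base: Interval, cuts: Sequence[Interval]) -> list[Interval]:
    """base minus the union of cuts."""
    s, e = base
    out: list[Interval] = []
    for cs, ce in merge(cuts):
        if ce <= s or cs >= e:
            continue
        if cs > s:
            out.append((s, cs))
        s = max(s, ce)
    if s < e:
        out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))
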