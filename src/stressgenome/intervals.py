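"""Half-open interval arithmetic on scaffold coordinates.

All coordinates in this package are 0-based half-open ``[start, end)``.
Conversion to/from 1-based inclusive conventions (GFF3, RepeatMasker)
happens only at I/O boundaries in :mod:`stressgenome.formats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic span ``[start, end)`` on a named scaffold."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold_id}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching ``(start, end)`` spans into a disjoint union."""
    ordered = sorted(spans)
    merged: list[tuple[int, int]] = []
    for start, end in ordered:
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def union_length(spans: Iterable[tuple[int, int]]) -> int:
    """Total number of bases covered by the union of the spans."""
    return sum(end - start for start, end in merge_spans(spans))


def gaps_between(spans: Sequence[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    """Sub-spans of ``[lo, hi)`` not covered by any input span."""
    gaps: list[tuple[int, int]] = []
    cursor = lo
    for start, end in merge_spans(spans):
        start, end = max(start, lo), min(end, hi)
        if start >= end:
            continue
        if start > cursor:
            gaps.append((cursor, start))
        cursor = max(cursor, end)
    if cursor < hi:
        gaps.append((cursor, hi))
    return gaps


def group_union_length(intervals: Iterable[Interval]) -> dict[str, int]:
    """Union length per scaffold."""
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_scaffold.setdefault(iv.scaffold_id, []).append((iv.start, iv.end))
    return {sid: union_length(spans) for sid, spans in by_scaffold.items()}
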