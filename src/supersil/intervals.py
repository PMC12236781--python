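"""Genomic interval primitives and interval-set algebra.

All coordinates are 0-based, half-open (BED convention). Strand is carried but
ignored by every operation here: regulatory elements are strandless objects.
Collections of intervals are plain Python lists of :class:`GenomicInterval`
(or subclass instances); the algebra below sorts and sweeps with numpy where
it matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Element",
    "sort_intervals",
    "merge_overlapping",
    "overlap_bp",
    "total_bp",
    "interval_set_jaccard",
    "midpoint",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


# Element classes used throughout: typical silencer/enhancer, super components,
# and the pre-classification placeholder.
ELEMENT_CLASSES = ("TS", "TE", "SS_component", "SE_component", "candidate")


@dataclass(frozen=True)
class Element:
    """A called regulatory element: an interval with a class label and scores.

    ``score`` is the (unitless) scorer output that passed screening; ``signal``
    is the mark signal attributed to the element (area under the track).
    """

    interval: GenomicInterval
    element_class: str = "candidate"
    score: float = 0.0
    signal: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class: {self.element_class}")
        if not math.isfinite(self.score):
            raise ValueError("element score must be finite")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def with_class(self, element_class: str) -> "Element":
        return replace(self, element_class=element_class)


def _as_interval(obj) -> GenomicInterval:
    return obj.interval if isinstance(obj, Element) else obj


def sort_intervals(intervals: Iterable) -> list:
    """Sort by (chrom, start, end); accepts intervals or elements."""
    return sorted(intervals, key=lambda x: (_as_interval(x).chrom, _as_interval(x).start, _as_interval(x).end))


def merge_overlapping(intervals: Iterable[GenomicInterval], gap: int = 0) -> list[GenomicInterval]:
    """Merge intervals closer than or exactly ``gap`` bp apart.

    Book-ended intervals (distance 0) merge at the default ``gap=0``; the
    union of covered bases is preserved.
    """
    ivs = sort_intervals(_as_interval(i) for i in intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def overlap_bp(a, b) -> int:
    """Base pairs shared by two intervals (0 when on different chromosomes)."""
    a, b = _as_interval(a), _as_interval(b)
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total covered bases of an interval set (merged first)."""
    return sum(len(iv) for iv in merge_overlapping(intervals))


def interval_set_jaccard(set_a: Sequence, set_b: Sequence) -> float | None:
    """Covered-base Jaccard index of two interval sets; None when both empty."""
    a = merge_overlapping(_as_interval(i) for i in set_a)
    b = merge_overlapping(_as_interval(i) for i in set_b)
    if not a and not b:
        return None
    inter = 0
    # sweep per chromosome
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for iv in a:
        for jv in by_chrom_b.get(iv.chrom, ()):
            inter += max(0, min(iv.end, jv.end) - max(iv.start, jv.start))
    union = total_bp(a) + total_bp(b) - inter
    return inter / union if union else None


def midpoint(obj) -> int:
    """Integer midpoint of an interval (floor)."""
    iv = _as_interval(obj)
    return (iv.start + iv.end) // 2


class IntervalIndex:
    """Per-chromosome sorted index supporting overlap queries by bisection.

    Intervals are kept as parallel numpy arrays; ``max_end`` prefixes make the
    any-overlap query O(log n + k) for sorted, mostly-disjoint inputs and
    correct (linear fallback) for arbitrary ones.
    """

    def __init__(self, intervals: Iterable):
        self._items: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        by_chrom: dict[str, list] = {}
        for obj in intervals:
            by_chrom.setdefault(_as_interval(obj).chrom, []).append(obj)
        for chrom, objs in by_chrom.items():
            objs.sort(key=lambda x: (_as_interval(x).start, _as_interval(x).end))
            starts = np.array([_as_interval(o).start for o in objs], dtype=np.int64)
            ends = np.array([_as_interval(o).end for o in objs], dtype=np.int64)
            self._items[chrom] = (starts, np.maximum.accumulate(ends), objs)
        self._raw_ends = {c: np.array([_as_interval(o).end for o in v[2]], dtype=np.int64)
                          for c, v in self._items.items()}

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        """All stored objects overlapping ``[start, end)`` on ``chrom``."""
        entry = self._items.get(chrom)
        if entry is None:
            return []
        starts, max_ends, objs = entry
        ends = self._raw_ends[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        lo = int(np.searchsorted(max_ends, start, side="right"))
        return [objs[i] for i in range(lo, hi) if ends[i] > start]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        entry = self._items.get(chrom)
        if entry is None:
            return False
        starts, max_ends, _ = entry
        ends = self._raw_ends[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        lo = int(np.searchsorted(max_ends, start, side="right"))
        return any(ends[i] > start for i in range(lo, hi))

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bases of ``[start, end)`` covered by any stored interval."""
        hits = self.overlapping(chrom, start, end)
        if not hits:
            return 0
        merged = merge_overlapping(
            GenomicInterval(chrom, max(start, _as_interval(h).start), min(end, _as_interval(h).end))
            for h in hits
        )
        return sum(len(iv) for iv in merged)
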