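"""Super-region calling by rank-ordering of stitched elements.

Elements are stitched when their gaps do not exceed the stitch distance
(12,500 bp by convention), each stitched region is assigned the summed mark
signal of its members, regions are ranked by signal, and the super/typical
split is made at the rank-ordering cutoff: with ranks and signals min-max
scaled to [0, 1], the cutoff is the point where a unit-slope line is tangent
to the rank-signal curve from below; regions with signal strictly above the
cutoff are super.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .intervals import Element, GenomicInterval, sort_intervals
from .io import SignalTrack

__all__ = ["SuperRegion", "stitch", "region_signal", "rose_cutoff", "classify_super",
           "call_super_regions"]


@dataclass
class SuperRegion:
    """A stitched run of elements with its total mark signal and rank."""

    interval: GenomicInterval
    members: list[Element]
    total_signal: float = 0.0
    rank: int = 0
    is_super: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def stitch(elements: Iterable[Element], stitch_distance: int = 12_500) -> list[SuperRegion]:
    """Group sorted, disjoint elements whose inter-element gaps are
    <= ``stitch_distance``; the region interval spans first to last member."""
    regions: list[SuperRegion] = []
    run: list[Element] = []
    for el in sort_intervals(elements):
        if run and el.chrom == run[-1].chrom and el.start - run[-1].end <= stitch_distance:
            run.append(el)
        else:
            if run:
                regions.append(_region_from(run))
            run = [el]
    if run:
        regions.append(_region_from(run))
    return regions


def _region_from(members: list[Element]) -> SuperRegion:
    iv = GenomicInterval(members[0].chrom, members[0].start, members[-1].end)
    return SuperRegion(interval=iv, members=list(members))


def region_signal(regions: Iterable[SuperRegion], track: SignalTrack,
                  control: SignalTrack | None = None) -> list[SuperRegion]:
    """Sum member-element signal areas per region and rank ascending.

    An optional control track's area is subtracted per member, floored at 0.
    """
    regions = list(regions)
    for region in regions:
        total = 0.0
        for el in region.members:
            area = track.summarize(el.interval, stat="area")
            if control is not None:
                area = max(0.0, area - control.summarize(el.interval, stat="area"))
            total += area
        region.total_signal = total
    regions.sort(key=lambda r: (r.total_signal, r.interval.chrom, r.interval.start))
    for i, region in enumerate(regions, start=1):
        region.rank = i
    return regions


def rose_cutoff(signals: Sequence[float]) -> float:
    """Rank-ordering cutoff of an ascending signal vector.

    Ranks and signals are min-max scaled to [0, 1]; the cutoff is the signal
    at the tangent point of a unit-slope line approaching the curve from
    below — the last index minimizing (scaled signal − scaled rank).
    Degenerate all-equal vectors put the cutoff at that value, so nothing is
    strictly above it and no region is super.
    """
    y = np.asarray(signals, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 signals for a rank-ordering cutoff")
    if np.any(np.diff(y) < 0):
        raise ValueError("signals must be ascending")
    x = np.arange(n, dtype=float) / (n - 1)
    span = y[-1] - y[0]
    ys = (y - y[0]) / span if span > 0 else np.zeros(n)
    d = ys - x
    # last index attaining the minimum, with a tolerance so exact ties
    # (e.g. a perfectly linear curve) resolve to the last rank despite
    # floating-point rounding
    ties = np.nonzero(d <= d.min() + 1e-12)[0]
    return float(y[int(ties[-1])])


def classify_super(regions: Sequence[SuperRegion], cutoff: float,
                   super_class: str = "SS_component",
                   typical_class: str = "TS") -> list[SuperRegion]:
    """Set ``is_super`` (signal strictly above cutoff) and relabel members.

    Members of super regions take ``super_class`` (SS_component or
    SE_component); all other elements take ``typical_class`` (TS or TE). The
    label partition is exhaustive and exclusive.
    """
    out = []
    for region in regions:
        is_super = region.total_signal > cutoff
        label = super_class if is_super else typical_class
        members = [el.with_class(label) for el in region.members]
        out.append(replace(region, is_super=is_super, members=members))
    return out


def call_super_regions(elements: Iterable[Element], track: SignalTrack,
                       stitch_distance: int = 12_500,
                       super_class: str = "SS_component",
                       typical_class: str = "TS",
                       control: SignalTrack | None = None) -> tuple[list[SuperRegion], float]:
    """Stitch, rank and classify in one pass; returns (regions, cutoff)."""
    regions = region_signal(stitch(elements, stitch_distance), track, control=control)
    cutoff = rose_cutoff([r.total_signal for r in regions])
    return classify_super(regions, cutoff, super_class, typical_class), cutoff
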