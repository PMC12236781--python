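"""TAD-boundary geometry: boundary flanks, shores, centers, counterpart
shores, and element/variant enrichment per segment class.

Boundaries are consumed as points (interval inputs are reduced to midpoints).
A position within 20 kb of its nearest boundary is in the boundary flank,
between 20 kb (exclusive) and 50 kb (inclusive) it is on a shore, and beyond
that it belongs to the TAD center. Each boundary side's shore can be mirrored
across the boundary to obtain its counterpart shore.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Element, GenomicInterval, midpoint
from .variants import VariantRecord

__all__ = [
    "TadSegment",
    "BOUNDARY_FLANK_BP",
    "SHORE_BP",
    "boundaries_from_intervals",
    "segment_class",
    "shores_of_boundary",
    "counterpart_shore",
    "segment_enrichment",
]

BOUNDARY_FLANK_BP = 20_000
SHORE_BP = 50_000


@dataclass(frozen=True)
class TadSegment:
    boundary_pos: int
    side: str  # "left" | "right"
    segment: str  # "boundary_flank" | "shore" | "center"
    interval: GenomicInterval
    truncated: bool = False


def boundaries_from_intervals(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    """Reduce boundary intervals to sorted midpoint arrays per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(midpoint(iv))
    return {c: np.array(sorted(ps), dtype=np.int64) for c, ps in by_chrom.items()}


def nearest_boundary_distance(position: int, boundaries: np.ndarray) -> int:
    if boundaries.size == 0:
        raise ValueError("no boundaries on chromosome")
    i = int(np.searchsorted(boundaries, position))
    cands = []
    if i > 0:
        cands.append(abs(position - int(boundaries[i - 1])))
    if i < boundaries.size:
        cands.append(abs(position - int(boundaries[i])))
    return min(cands)


def segment_class(position: int, boundaries: np.ndarray,
                  flank_bp: int = BOUNDARY_FLANK_BP, shore_bp: int = SHORE_BP) -> str:
    """Segment label of a position by distance d to the nearest boundary:
    d <= 20 kb boundary_flank; 20 kb < d <= 50 kb shore; else center."""
    d = nearest_boundary_distance(position, boundaries)
    if d <= flank_bp:
        return "boundary_flank"
    if d <= shore_bp:
        return "shore"
    return "center"


def shores_of_boundary(chrom: str, boundary_pos: int,
                       chrom_size: int | None = None) -> list[TadSegment]:
    """The two shore segments of one boundary (possibly truncated at the
    chromosome edges)."""
    out = []
    for side in ("left", "right"):
        if side == "left":
            start, end = boundary_pos - SHORE_BP, boundary_pos - BOUNDARY_FLANK_BP
        else:
            start, end = boundary_pos + BOUNDARY_FLANK_BP, boundary_pos + SHORE_BP
        truncated = False
        if start < 0:
            start, truncated = 0, True
        if chrom_size is not None and end > chrom_size:
            end, truncated = chrom_size, True
        if end <= start:
            continue
        out.append(TadSegment(boundary_pos, side, "shore",
                              GenomicInterval(chrom, start, end), truncated))
    return out


def counterpart_shore(shore: TadSegment, chrom_size: int | None = None) -> TadSegment:
    """Mirror a shore across its boundary; an involution when untruncated."""
    b = shore.boundary_pos
    start = 2 * b - shore.interval.end
    end = 2 * b - shore.interval.start
    truncated = False
    if start < 0:
        start, truncated = 0, True
    if chrom_size is not None and end > chrom_size:
        end, truncated = chrom_size, True
    side = "right" if shore.side == "left" else "left"
    return TadSegment(b, side, "shore", GenomicInterval(shore.interval.chrom, start, end),
                      truncated)


SEGMENT_CLASSES = ("boundary_flank", "shore", "center")


def segment_enrichment(items_by_class: Mapping[str, Sequence],
                       boundaries: Mapping[str, np.ndarray],
                       chrom_sizes: Mapping[str, int],
                       background: Sequence | None = None) -> pd.DataFrame:
    """Per (item class x segment class): counts, fractions, and fold
    enrichment against the genome-wide segment base composition (or against
    a supplied background item set).

    Items may be elements (assigned by midpoint) or point variants.
    """
    seg_bases = _segment_base_composition(boundaries, chrom_sizes)
    total_bases = sum(seg_bases.values())
    base_frac = {seg: seg_bases[seg] / total_bases for seg in SEGMENT_CLASSES}

    bg_frac = None
    if background is not None:
        bg_counts = _count_by_segment(background, boundaries)
        bg_total = sum(bg_counts.values())
        if bg_total:
            bg_frac = {seg: bg_counts[seg] / bg_total for seg in SEGMENT_CLASSES}

    rows = []
    for cls, items in items_by_class.items():
        counts = _count_by_segment(items, boundaries)
        n = sum(counts.values())
        for seg in SEGMENT_CLASSES:
            frac = counts[seg] / n if n else np.nan
            expected = (bg_frac or base_frac)[seg]
            rows.append({
                "item_class": cls, "segment": seg, "count": counts[seg], "n": n,
                "fraction": frac, "expected_fraction": expected,
                "fold": frac / expected if n and expected > 0 else np.nan,
            })
    return pd.DataFrame(rows)


def _item_position(item) -> tuple[str, int]:
    if isinstance(item, VariantRecord):
        return item.chrom, item.position
    if isinstance(item, Element):
        return item.chrom, midpoint(item)
    return item.chrom, midpoint(item)


def _count_by_segment(items: Sequence, boundaries: Mapping[str, np.ndarray]) -> dict[str, int]:
    counts = {seg: 0 for seg in SEGMENT_CLASSES}
    for item in items:
        chrom, pos = _item_position(item)
        bnd = boundaries.get(chrom)
        if bnd is None or bnd.size == 0:
            continue
        counts[segment_class(pos, bnd)] += 1
    return counts


def _segment_base_composition(boundaries: Mapping[str, np.ndarray],
                              chrom_sizes: Mapping[str, int],
                              sample_step: int = 1_000) -> dict[str, int]:
    """Base counts per segment class, computed exactly from the distance
    geometry: between two consecutive boundaries the nearest-boundary
    distance is piecewise linear, so class extents follow from interval
    arithmetic on half-segments."""
    counts = {seg: 0 for seg in SEGMENT_CLASSES}

    def add_halfseg(span: int):
        # one side of a boundary, reaching `span` bases before the midpoint
        # to the neighboring boundary (or the chromosome edge).
        flank = min(span, BOUNDARY_FLANK_BP)
        shore = min(max(span - BOUNDARY_FLANK_BP, 0), SHORE_BP - BOUNDARY_FLANK_BP)
        center = max(span - SHORE_BP, 0)
        counts["boundary_flank"] += flank
        counts["shore"] += shore
        counts["center"] += center

    for chrom, bnd in boundaries.items():
        size = chrom_sizes[chrom]
        if bnd.size == 0:
            continue
        edges = [0] + [int((bnd[i] + bnd[i + 1]) // 2) for i in range(bnd.size - 1)] + [size]
        for i, b in enumerate(bnd):
            add_halfseg(int(b) - edges[i])        # left side
            add_halfseg(edges[i + 1] - int(b))    # right side
    return counts
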