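"""CpG-island classification, methylation summaries and repression-model
contact signatures.

An element is CGI-class when its total overlap with (merged) CpG islands
strictly exceeds 200 bp. Two repression mechanisms leave distinct contact
signatures: condensation silencers (model I) deplete chromatin contacts in
their +/-50 kb proximity, while promoter-shielding silencers (model II) carry
dense contacts themselves but cut their target promoters off from enhancer
interactions. Both are reported as continuous signatures (flank contact
density, promoter enhancer-contact counts), not hard assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Element, GenomicInterval, IntervalIndex, merge_overlapping
from .io import ContactSet, SignalTrack

__all__ = [
    "CgiClassification",
    "classify_cgi",
    "methylation_mean",
    "element_contact_density",
    "contact_class_pair_table",
    "flank_contact_enrichment",
    "promoter_contact_profile",
]


@dataclass(frozen=True)
class CgiClassification:
    element_key: str
    is_cgi: bool
    overlap_bp: int


def classify_cgi(element: Element, cgi_index: IntervalIndex,
                 min_overlap: int = 200) -> CgiClassification:
    """CGI-class when total CpG-island overlap is strictly > ``min_overlap``.

    Callers build ``cgi_index`` from merged CGI intervals (``IntervalIndex``
    of ``merge_overlapping(cgis)``).
    """
    ov = cgi_index.overlap_bp(element.chrom, element.start, element.end)
    key = element.name or f"{element.chrom}:{element.start}-{element.end}"
    return CgiClassification(key, ov > min_overlap, ov)


def methylation_mean(element: Element, methylation: SignalTrack) -> float | None:
    """Unweighted mean methylation fraction over CpG sites inside the
    element; None when the element contains no profiled site.

    The track carries one segment per CpG site with a value in [0, 1].
    """
    vals = []
    for chrom, start, end, value in methylation.segments():
        if chrom != element.chrom:
            continue
        if start < element.end and end > element.start:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"methylation value outside [0,1]: {value}")
            vals.append(value)
    return float(np.mean(vals)) if vals else None


class AnchorIndex:
    """Sorted per-chromosome anchor array for fast contact-overlap queries."""

    def __init__(self, contacts: ContactSet):
        anchors: dict[str, list[tuple[int, int, int]]] = {}
        for i, c in enumerate(contacts):
            anchors.setdefault(c.chrom1, []).append((c.start1, c.end1, i))
            anchors.setdefault(c.chrom2, []).append((c.start2, c.end2, i))
        self._data = {}
        for chrom, rows in anchors.items():
            rows.sort()
            self._data[chrom] = (np.array([r[0] for r in rows], dtype=np.int64),
                                 np.array([r[1] for r in rows], dtype=np.int64),
                                 np.array([r[2] for r in rows], dtype=np.int64))

    def contact_ids(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of contacts with >=1 anchor overlapping [start, end)."""
        entry = self._data.get(chrom)
        if entry is None:
            return np.array([], dtype=np.int64)
        starts, ends, ids = entry
        hi = int(np.searchsorted(starts, end, side="left"))
        mask = ends[:hi] > start
        return np.unique(ids[:hi][mask])

    def contact_ids_excluding(self, chrom: str, start: int, end: int,
                              ex_start: int, ex_end: int) -> np.ndarray:
        """Contacts with an anchor overlapping [start, end) while that anchor
        does not overlap [ex_start, ex_end)."""
        entry = self._data.get(chrom)
        if entry is None:
            return np.array([], dtype=np.int64)
        starts, ends, ids = entry
        hi = int(np.searchsorted(starts, end, side="left"))
        s, e, i = starts[:hi], ends[:hi], ids[:hi]
        mask = (e > start) & ~((s < ex_end) & (e > ex_start))
        return np.unique(i[mask])


def element_contact_density(elements_by_class: Mapping[str, Sequence[Element]],
                            contacts: ContactSet) -> pd.DataFrame:
    """Mean number of contacts with at least one anchor in an element, per
    element class/subclass."""
    index = AnchorIndex(contacts)
    rows = []
    for cls, elements in elements_by_class.items():
        counts = [index.contact_ids(el.chrom, el.start, el.end).size
                  for el in elements]
        rows.append({"element_class": cls, "n_elements": len(counts),
                     "mean_contacts": float(np.mean(counts)) if counts else np.nan})
    return pd.DataFrame(rows)


def contact_class_pair_table(elements_by_class: Mapping[str, Sequence[Element]],
                             contacts: ContactSet) -> pd.DataFrame:
    """Counts of contacts whose two anchors fall in elements of classes
    (a, b); unordered class pairs, both-anchor hits only."""
    indexes = {cls: IntervalIndex(els) for cls, els in elements_by_class.items()}
    counts: dict[tuple[str, str], int] = {}
    for c in contacts:
        hits1 = [cls for cls, idx in indexes.items()
                 if idx.any_overlap(c.chrom1, c.start1, c.end1)]
        hits2 = [cls for cls, idx in indexes.items()
                 if idx.any_overlap(c.chrom2, c.start2, c.end2)]
        for a in hits1:
            for b in hits2:
                key = tuple(sorted((a, b)))
                counts[key] = counts.get(key, 0) + 1
    rows = [{"class_a": a, "class_b": b, "count": n}
            for (a, b), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["class_a", "class_b", "count"])


def flank_contact_enrichment(element: Element, contacts: ContactSet,
                             flank: int = 50_000,
                             index: "AnchorIndex | None" = None) -> float:
    """Contacts anchored in the element's +/-flank (element body excluded),
    normalized to contacts per 10 kb of flank.

    An anchor counts when it overlaps a flank window without overlapping the
    element body itself. A prebuilt :class:`AnchorIndex` may be passed when
    scoring many elements against the same contact set.
    """
    index = index if index is not None else AnchorIndex(contacts)
    left = (max(0, element.start - flank), element.start)
    right = (element.end, element.end + flank)
    flank_bp = (left[1] - left[0]) + (right[1] - right[0])
    if flank_bp == 0:
        return 0.0
    ids = [index.contact_ids_excluding(element.chrom, lo, hi,
                                       element.start, element.end)
           for lo, hi in (left, right) if lo < hi]
    n = np.unique(np.concatenate(ids)).size if ids else 0
    return n / (flank_bp / 10_000)


def promoter_contact_profile(promoters_by_group: Mapping[str, Sequence[GenomicInterval]],
                             contacts: ContactSet,
                             enhancers: Sequence[Element]) -> pd.DataFrame:
    """Per promoter group: mean total contact count and mean count of
    contacts whose distal anchor overlaps an enhancer."""
    enh_index = IntervalIndex(enhancers)
    contact_list = list(contacts)
    anchor_index = AnchorIndex(contacts)
    rows = []
    for group, promoters in promoters_by_group.items():
        totals, enh_counts = [], []
        for prom in promoters:
            ids = anchor_index.contact_ids(prom.chrom, prom.start, prom.end)
            enh = 0
            for i in ids:
                c = contact_list[int(i)]
                anchors = ((c.chrom1, c.start1, c.end1), (c.chrom2, c.start2, c.end2))
                for a, b in (anchors, anchors[::-1]):
                    if a[0] == prom.chrom and a[1] < prom.end and a[2] > prom.start:
                        if enh_index.any_overlap(*b):
                            enh += 1
                        break
            totals.append(ids.size)
            enh_counts.append(enh)
        rows.append({"group": group, "n_promoters": len(totals),
                     "mean_total_contacts": float(np.mean(totals)) if totals else np.nan,
                     "mean_enhancer_contacts": float(np.mean(enh_counts)) if enh_counts else np.nan})
    return pd.DataFrame(rows)
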