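"""Cross-cell-type activity encoding and cooperativity metrics.

Each element gets an activity label per cell type: +1 when it overlaps only
active-mark (H3K27ac) peaks there, −1 when only repressive-mark (H3K27me3)
peaks, and 0 when both marks are present (uncertain) or neither is.
Cooperativity between two elements is the cosine similarity of their activity
rows; TF-binding-site similarity is the Jaccard index of their binary TF
occupancy rows. Background pairs for comparison are typical elements sampled
to match the inter-element distance distribution of super-region component
pairs.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Element, IntervalIndex, midpoint
from .supercall import SuperRegion

__all__ = [
    "encode_activity",
    "build_activity_matrix",
    "build_tfbs_matrix",
    "cooperativity",
    "tfbs_similarity",
    "region_pair_scores",
    "matched_background_pairs",
    "fraction_tfs_multibound",
]


def encode_activity(element: Element,
                    ac_index: IntervalIndex | None,
                    me_index: IntervalIndex | None) -> int:
    """Activity of one element in one cell type: {+1, 0, −1}."""
    has_ac = ac_index.any_overlap(element.chrom, element.start, element.end) if ac_index else False
    has_me = me_index.any_overlap(element.chrom, element.start, element.end) if me_index else False
    if has_ac and not has_me:
        return 1
    if has_me and not has_ac:
        return -1
    return 0  # both (uncertain) or neither


def build_activity_matrix(elements: Sequence[Element],
                          ac_peaks_by_cell: Mapping[str, Iterable],
                          me_peaks_by_cell: Mapping[str, Iterable]) -> pd.DataFrame:
    """Elements x cell types matrix with entries in {−1, 0, 1}.

    Rows are indexed by element name (or position string); columns are the
    union of cell types appearing in either peak mapping, sorted.
    """
    cells = sorted(set(ac_peaks_by_cell) | set(me_peaks_by_cell))
    ac_idx = {c: IntervalIndex(ac_peaks_by_cell[c]) for c in ac_peaks_by_cell}
    me_idx = {c: IntervalIndex(me_peaks_by_cell[c]) for c in me_peaks_by_cell}
    rows = {}
    for el in elements:
        key = el.name or f"{el.chrom}:{el.start}-{el.end}"
        rows[key] = [encode_activity(el, ac_idx.get(c), me_idx.get(c)) for c in cells]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cells, dtype=np.int8)


def build_tfbs_matrix(elements: Sequence[Element],
                      tf_peaks: Mapping[str, Iterable]) -> pd.DataFrame:
    """Elements x TFs binary occupancy matrix from TF ChIP-seq peak sets."""
    tfs = sorted(tf_peaks)
    idx = {tf: IntervalIndex(tf_peaks[tf]) for tf in tfs}
    rows = {}
    for el in elements:
        key = el.name or f"{el.chrom}:{el.start}-{el.end}"
        rows[key] = [int(idx[tf].any_overlap(el.chrom, el.start, el.end)) for tf in tfs]
    return pd.DataFrame.from_dict(rows, orient="index", columns=tfs, dtype=np.int8)


def cooperativity(a_i: Sequence[int], a_j: Sequence[int]) -> float | None:
    """Cosine similarity of two {−1,0,1} activity rows; None when either row
    is all-zero (cosine undefined — excluded from aggregates rather than
    reported as a fake zero)."""
    a_i = np.asarray(a_i, dtype=float)
    a_j = np.asarray(a_j, dtype=float)
    if a_i.shape != a_j.shape:
        raise ValueError(f"activity rows differ in length: {a_i.size} vs {a_j.size}")
    ni, nj = np.linalg.norm(a_i), np.linalg.norm(a_j)
    if ni == 0 or nj == 0:
        return None
    return float(np.dot(a_i, a_j) / (ni * nj))


def tfbs_similarity(t_i: Sequence[int], t_j: Sequence[int]) -> float | None:
    """Jaccard similarity of two binary TF occupancy rows; None when both
    rows are empty."""
    t_i = np.asarray(t_i, dtype=float)
    t_j = np.asarray(t_j, dtype=float)
    if t_i.shape != t_j.shape:
        raise ValueError(f"TFBS rows differ in length: {t_i.size} vs {t_j.size}")
    inter = float(np.sum(t_i * t_j))
    union = float(np.sum(t_i + t_j - t_i * t_j))
    if union == 0:
        return None
    return inter / union


def _row_key(el: Element) -> str:
    return el.name or f"{el.chrom}:{el.start}-{el.end}"


def region_pair_scores(region: SuperRegion, matrix: pd.DataFrame,
                       metric=cooperativity) -> list[float]:
    """All C(m, 2) pairwise scores among a region's members; undefined pairs
    are excluded. Regions with fewer than 2 members yield an empty list."""
    if region.n_members < 2:
        return []
    scores = []
    for el_a, el_b in itertools.combinations(region.members, 2):
        s = metric(matrix.loc[_row_key(el_a)].to_numpy(),
                   matrix.loc[_row_key(el_b)].to_numpy())
        if s is not None:
            scores.append(s)
    return scores


def pair_distance(el_a: Element, el_b: Element) -> int:
    return abs(midpoint(el_a) - midpoint(el_b))


# two-octave bins from 1 kb to 1 Mb, open-ended on both sides
_DISTANCE_BINS = np.array([0.0, 1_000.0, 4_000.0, 16_000.0, 64_000.0,
                           256_000.0, 1_048_576.0, np.inf])


def matched_background_pairs(component_pairs: Sequence[tuple[Element, Element]],
                             ts_pool: Sequence[Element],
                             seed: int,
                             bins: np.ndarray = _DISTANCE_BINS,
                             ) -> tuple[list[tuple[Element, Element]],
                                        list[tuple[Element, Element]]]:
    """Sample typical-element pairs whose inter-pair distances match, per
    log-spaced distance bin, the distances of the given component pairs.

    Candidate background pairs are same-chromosome typical-element pairs.
    Returns ``(background_pairs, kept_component_pairs)``: a bin the pool
    cannot fill is dropped from BOTH sides (with a warning), so the two
    returned lists always have identical per-bin distance histograms.
    """
    rng = np.random.default_rng(seed)
    target_dists = np.array([pair_distance(a, b) for a, b in component_pairs])
    target_counts, _ = np.histogram(target_dists, bins=bins)

    pool = sorted(ts_pool, key=lambda e: (e.chrom, e.start))
    candidates: list[list[tuple[Element, Element]]] = [[] for _ in range(len(bins) - 1)]
    by_chrom: dict[str, list[Element]] = {}
    for el in pool:
        by_chrom.setdefault(el.chrom, []).append(el)
    for els in by_chrom.values():
        for a, b in itertools.combinations(els, 2):
            d = pair_distance(a, b)
            k = int(np.searchsorted(bins, d, side="right") - 1)
            if 0 <= k < len(candidates):
                candidates[k].append((a, b))

    sampled: list[tuple[Element, Element]] = []
    kept: list[tuple[Element, Element]] = []
    for k, want in enumerate(target_counts):
        if want == 0:
            continue
        have = candidates[k]
        if len(have) < want:
            warnings.warn(f"distance bin {k} unfillable ({len(have)} < {want}); "
                          "dropped from both sides", stacklevel=2)
            continue
        take = rng.choice(len(have), size=int(want), replace=False)
        sampled.extend(have[i] for i in sorted(take))
        kept.extend(p for p, d in zip(component_pairs, target_dists)
                    if bins[k] <= d < bins[k + 1])
    return sampled, kept


def fraction_tfs_multibound(region: SuperRegion, tfbs: pd.DataFrame) -> float:
    """Fraction of all profiled TFs bound in at least two of the region's
    member elements (denominator: every TF column in the matrix)."""
    if tfbs.shape[1] == 0:
        raise ValueError("TFBS matrix has no TF columns")
    keys = [_row_key(el) for el in region.members]
    sub = tfbs.loc[keys]
    multibound = (sub.sum(axis=0) >= 2).sum()
    return float(multibound) / tfbs.shape[1]
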