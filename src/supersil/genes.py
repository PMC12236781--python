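"""Element-to-gene association, expression summaries and locus enrichment.

Elements are linked to genes two ways: the single most proximal gene (by
midpoint-to-TSS distance, ties broken to the lexicographically smaller gene
id) and the set of genes whose promoters share a chromatin contact with the
element. Gene-level summaries cover tissue specificity (tau) and per-class
expression across cell types; locus enrichment compares element classes
against a background set inside named gene-locus interval sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Element, GenomicInterval, IntervalIndex, midpoint
from .io import ContactSet, GeneRecord

__all__ = [
    "GeneAssociation",
    "classify_genomic_context",
    "nearest_gene",
    "contact_genes",
    "tau",
    "class_expression_summary",
    "locus_enrichment",
]


@dataclass(frozen=True)
class GeneAssociation:
    element_key: str
    gene_id: str
    mode: str  # "proximal" | "contact"
    distance: int | None = None
    contact_count: int | None = None


def _el_key(el: Element) -> str:
    return el.name or f"{el.chrom}:{el.start}-{el.end}"


def classify_genomic_context(element: Element, genes: Sequence[GeneRecord],
                             promoter_flank: int = 2_000) -> str:
    """Classify an element as promoter / intragenic / intergenic.

    Promoter when overlapping any TSS +/- flank; else intragenic when
    overlapping a gene body; else intergenic.
    """
    for g in genes:
        if g.chrom != element.chrom:
            continue
        if element.start < g.tss + promoter_flank and element.end > g.tss - promoter_flank:
            return "promoter"
    for g in genes:
        if g.chrom == element.chrom and element.start < g.body.end and element.end > g.body.start:
            return "intragenic"
    return "intergenic"


def nearest_gene(element: Element, genes: Sequence[GeneRecord]) -> GeneAssociation | None:
    """Most proximal gene by |element midpoint − TSS|; deterministic ties to
    the smaller gene id. None when the element's chromosome has no gene."""
    mid = midpoint(element)
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != element.chrom:
            continue
        d = abs(mid - g.tss)
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    if best is None:
        return None
    return GeneAssociation(_el_key(element), best[1], "proximal", distance=best[0])


def contact_genes(element: Element, contacts: ContactSet, genes: Sequence[GeneRecord],
                  promoter_flank: int = 2_000) -> dict[str, int]:
    """Genes whose promoter (TSS +/- flank) sits on the anchor paired with an
    anchor overlapping the element; returns gene id -> contact count."""
    prom_lookup: dict[tuple[str, int, int], list[str]] = {}
    for g in genes:
        iv = GenomicInterval(g.chrom, max(0, g.tss - promoter_flank), g.tss + promoter_flank)
        prom_lookup.setdefault((iv.chrom, iv.start, iv.end), []).append(g.gene_id)
    promoters = IntervalIndex(GenomicInterval(c, s, e) for c, s, e in prom_lookup)
    counts: dict[str, int] = {}
    for c in contacts:
        anchors = ((c.chrom1, c.start1, c.end1), (c.chrom2, c.start2, c.end2))
        for a, b in (anchors, anchors[::-1]):
            if a[0] == element.chrom and a[1] < element.end and a[2] > element.start:
                for hit in promoters.overlapping(*b):
                    for gid in prom_lookup[(hit.chrom, hit.start, hit.end)]:
                        counts[gid] = counts.get(gid, 0) + 1
    return counts


def tau(expression: Sequence[float]) -> float | None:
    """Tissue-specificity index in [0, 1]: 0 for uniform expression, 1 for
    single-cell-type expression.

    tau = sum_i (1 − x_i / max) / (N − 1). Vectors containing negative values
    (log-scale input) are shifted by their minimum first; all-zero vectors
    have undefined specificity and return None.
    """
    x = np.asarray(expression, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires at least two cell types")
    if np.min(x) < 0:
        x = x - np.min(x)
    m = np.max(x)
    if m == 0:
        return None
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def class_expression_summary(associations_by_class: Mapping[str, Iterable[GeneAssociation]],
                             expression: Mapping[str, Mapping[str, float]],
                             reference_class: str = "TS") -> pd.DataFrame:
    """Per element class and cell type: mean/median associated-gene expression
    and the ratio of the class mean to the reference class mean.

    Also attaches a two-sided rank-sum p-value of each class against the
    reference class per cell type.
    """
    values: dict[str, dict[str, list[float]]] = {}
    for cls, assocs in associations_by_class.items():
        per_cell: dict[str, list[float]] = {}
        for a in assocs:
            for cell, v in expression.get(a.gene_id, {}).items():
                per_cell.setdefault(cell, []).append(float(v))
        values[cls] = per_cell

    ref = values.get(reference_class, {})
    rows = []
    for cls, per_cell in values.items():
        for cell, vals in sorted(per_cell.items()):
            ref_vals = ref.get(cell, [])
            ref_mean = float(np.mean(ref_vals)) if ref_vals else np.nan
            mean = float(np.mean(vals))
            if ref_vals and cls != reference_class and len(vals) > 1 and len(ref_vals) > 1:
                p = float(stats.ranksums(vals, ref_vals).pvalue)
            else:
                p = np.nan
            rows.append({
                "element_class": cls, "cell_type": cell, "n_genes": len(vals),
                "mean": mean, "median": float(np.median(vals)),
                "ratio_vs_reference": mean / ref_mean if ref_mean and np.isfinite(ref_mean) and ref_mean != 0 else np.nan,
                "ranksum_p": p,
            })
    return pd.DataFrame(rows)


def locus_enrichment(elements_by_class: Mapping[str, Sequence[Element]],
                     locus_sets: Mapping[str, Sequence[GenomicInterval]],
                     background: Sequence[Element],
                     flank: int = 50_000) -> pd.DataFrame:
    """Fold enrichment of each element class inside each named locus set.

    A locus is a gene body extended by ``flank`` on both sides (callers pass
    raw gene-body intervals). fold = (class fraction in loci) / (background
    fraction in loci), with an exact binomial test of the class count at the
    background rate. A zero background fraction leaves the fold undefined.
    """
    rows = []
    for set_name, loci in locus_sets.items():
        flanked = [GenomicInterval(l.chrom, max(0, l.start - flank), l.end + flank)
                   for l in loci]
        index = IntervalIndex(flanked)

        def frac(els: Sequence[Element]) -> tuple[int, int]:
            k = sum(1 for e in els if index.any_overlap(e.chrom, e.start, e.end))
            return k, len(els)

        bg_k, bg_n = frac(background)
        bg_frac = bg_k / bg_n if bg_n else np.nan
        for cls, els in elements_by_class.items():
            k, n = frac(els)
            if n == 0 or not np.isfinite(bg_frac) or bg_frac == 0:
                fold, p = np.nan, np.nan
            else:
                fold = (k / n) / bg_frac
                p = float(stats.binomtest(k, n, bg_frac).pvalue)
            rows.append({"locus_set": set_name, "element_class": cls, "k": k, "n": n,
                         "background_fraction": bg_frac, "fold": fold, "binomial_p": p})
    return pd.DataFrame(rows)
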