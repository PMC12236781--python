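"""Silencer/enhancer conversions between a normal cell type and cancer samples.

A normal-cell element "converts" when it overlaps a cancer-sample super
region of the opposite regulatory sign (e.g. a normal super-silencer
component overlapping a cancer super-enhancer region) in at least one
sample; a conversion is "recurrent" when supported by strictly more than
half of the samples. Downstream summaries cover associated-gene expression
fold changes, fractions of genes responding to a BET-inhibitor-style
treatment time course, and bin-level chromatin-contact retention between
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Element, IntervalIndex
from .io import ContactSet
from .supercall import SuperRegion

__all__ = [
    "ConversionRecord",
    "CONVERSION_DIRECTIONS",
    "detect_conversions",
    "recurrence",
    "associated_gene_fold_change",
    "response_fractions",
    "contact_retention",
]

# direction labels by (source element class, opposite-sign cancer super kind)
CONVERSION_DIRECTIONS = {
    "SS_component": "SS_to_SE",
    "TS": "TS_to_SE",
    "TE": "TE_to_SE",
    "SE_component": "SE_to_SS",
}


@dataclass(frozen=True)
class ConversionRecord:
    source: Element
    direction: str
    supporting_samples: tuple[str, ...]
    n_samples: int
    associated_gene: str = ""

    @property
    def recurrent(self) -> bool:
        return len(self.supporting_samples) > self.n_samples / 2

    @property
    def support_fraction(self) -> float:
        return len(self.supporting_samples) / self.n_samples


def detect_conversions(source_elements: Sequence[Element],
                       cancer_regions_by_sample: Mapping[str, Sequence],
                       min_overlap_bp: int = 1,
                       gene_by_element: Mapping[str, str] | None = None,
                       ) -> list[ConversionRecord]:
    """Find source elements overlapping opposite-sign cancer super regions.

    ``cancer_regions_by_sample`` maps sample id to that sample's called super
    regions of the opposite sign (intervals, elements or SuperRegions). An
    element converts when the overlap reaches ``min_overlap_bp`` in at least
    one sample; all supporting samples are recorded.
    """
    samples = sorted(cancer_regions_by_sample)
    indexes = {}
    for sample in samples:
        regions = [r.interval if isinstance(r, SuperRegion) else r
                   for r in cancer_regions_by_sample[sample]]
        indexes[sample] = IntervalIndex(regions)
    records = []
    for el in source_elements:
        direction = CONVERSION_DIRECTIONS.get(el.element_class)
        if direction is None:
            continue
        supporters = tuple(
            s for s in samples
            if indexes[s].overlap_bp(el.chrom, el.start, el.end) >= min_overlap_bp)
        if supporters:
            gene = (gene_by_element or {}).get(
                el.name or f"{el.chrom}:{el.start}-{el.end}", "")
            records.append(ConversionRecord(el, direction, supporters, len(samples), gene))
    return records


def recurrence(record: ConversionRecord) -> tuple[bool, float]:
    """(recurrent flag, support fraction): recurrent when supporters exceed a
    strict majority of samples."""
    if record.n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return record.recurrent, record.support_fraction


def associated_gene_fold_change(records: Sequence[ConversionRecord],
                                expr_normal: Mapping[str, float],
                                expr_cancer: Mapping[str, float],
                                pseudocount: float = 1.0) -> pd.DataFrame:
    """Linear-scale expression fold change (cancer + eps) / (normal + eps)
    of each record's associated gene, with per-direction mean folds.

    Records whose gene has no expression value are skipped but counted.
    """
    rows = []
    skipped = 0
    for r in records:
        g = r.associated_gene
        if not g or g not in expr_normal or g not in expr_cancer:
            skipped += 1
            continue
        fold = (expr_cancer[g] + pseudocount) / (expr_normal[g] + pseudocount)
        rows.append({"direction": r.direction, "gene": g, "fold": fold,
                     "recurrent": r.recurrent})
    df = pd.DataFrame(rows, columns=["direction", "gene", "fold", "recurrent"])
    df.attrs["n_skipped_missing_expression"] = skipped
    return df


def response_fractions(timecourse: pd.DataFrame,
                       gene_classes: Mapping[str, str],
                       alpha: float = 0.01) -> pd.DataFrame:
    """Fractions of genes significantly down-/up-regulated per gene class and
    timepoint under a treatment vs control time course.

    ``timecourse`` columns: gene, timepoint, condition ("treated"/"control"),
    replicate, value. Per gene and timepoint a two-sample t-test compares
    treated vs control replicates; a gene counts as down (up) when p < alpha
    and the treated mean is below (above) the control mean.
    """
    results = []
    for (gene, tp), grp in timecourse.groupby(["gene", "timepoint"]):
        treated = grp.loc[grp.condition == "treated", "value"].to_numpy(dtype=float)
        control = grp.loc[grp.condition == "control", "value"].to_numpy(dtype=float)
        if len(treated) < 2 or len(control) < 2:
            raise ValueError(f"gene {gene!r} needs >=2 replicates per condition")
        if np.ptp(treated) == 0 and np.ptp(control) == 0 and treated.mean() == control.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(treated, control).pvalue)
            if not np.isfinite(p):
                p = 1.0
        results.append({"gene": gene, "timepoint": tp,
                        "delta": float(treated.mean() - control.mean()), "p": p})
    res = pd.DataFrame(results)
    rows = []
    for tp, grp in res.groupby("timepoint"):
        grp = grp.assign(cls=[gene_classes.get(g, "other") for g in grp.gene])
        for cls, sub in grp.groupby("cls"):
            sig = sub.p < alpha
            n = len(sub)
            rows.append({
                "gene_class": cls, "timepoint": tp, "n_genes": n,
                "frac_down": float(np.mean(sig & (sub.delta < 0))) if n else np.nan,
                "frac_up": float(np.mean(sig & (sub.delta > 0))) if n else np.nan,
            })
    return pd.DataFrame(rows)


def contact_retention(contacts_ref: ContactSet, contacts_other: ContactSet,
                      anchor_elements_by_class: Mapping[str, Sequence[Element]],
                      ) -> pd.DataFrame:
    """Fraction of reference contacts anchored at class elements that persist
    (same bin pair) in another contact set.

    Both sets must share the bin size; identity is exact at bin resolution.
    """
    if contacts_ref.bin_size != contacts_other.bin_size:
        raise ValueError(
            f"bin size mismatch: {contacts_ref.bin_size} vs {contacts_other.bin_size}")
    other_bins = contacts_other.bin_pairs()
    rows = []
    for cls, elements in anchor_elements_by_class.items():
        index = IntervalIndex(elements)
        total = retained = 0
        for c in contacts_ref:
            anchored = (index.any_overlap(c.chrom1, c.start1, c.end1)
                        or index.any_overlap(c.chrom2, c.start2, c.end2))
            if not anchored:
                continue
            total += 1
            key = (c.chrom1, contacts_ref.bin_of(c.start1),
                   c.chrom2, contacts_ref.bin_of(c.start2))
            if key in other_bins:
                retained += 1
        rows.append({"element_class": cls, "n_contacts": total, "n_retained": retained,
                     "retained_fraction": retained / total if total else np.nan})
    return pd.DataFrame(rows)
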