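"""Disease-variant enrichment in regulatory elements.

Covers GWAS SNP handling (linkage-disequilibrium expansion at r² > 0.8,
replication across studies), somatic SNV summaries (density per kb, cancer
class fractions, donor recurrence), translocation breakpoints (the in /
by-±50kb / outside partition and the partner element-class table), and the
exact binomial enrichment test used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Element, GenomicInterval, IntervalIndex, merge_overlapping, total_bp
from .io import normalize_chrom

__all__ = [
    "VariantRecord",
    "LdPair",
    "read_variant_table",
    "read_ld_table",
    "ld_expand",
    "density_per_kb",
    "class_fraction",
    "recurrent_fraction",
    "replicated_fraction",
    "proximal_partition",
    "translocation_partner_distribution",
    "binomial_enrichment",
    "variants_in",
]

VARIANT_KINDS = ("GWAS_SNP", "somatic_SNV", "TLBP")


@dataclass(frozen=True)
class VariantRecord:
    """A point variant: GWAS SNP, somatic SNV, or translocation breakpoint.

    ``position`` is 0-based internally (1-based table inputs are shifted at
    the reader). TLBP records carry exactly one partner locus.
    """

    chrom: str
    position: int
    kind: str
    var_id: str = ""
    variant_class: str = ""  # cancer type or trait class
    donor_id: str = ""
    study_id: str = ""
    partner_chrom: str = ""
    partner_position: int = -1

    def __post_init__(self):
        if self.kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind: {self.kind}")
        if self.kind == "TLBP" and self.partner_position < 0:
            raise ValueError("TLBP records require a partner breakpoint")


@dataclass(frozen=True)
class LdPair:
    snp_a: str
    snp_b: str
    r2: float
    population: str = ""

    def __post_init__(self):
        if not 0 <= self.r2 <= 1:
            raise ValueError(f"r2 outside [0,1]: {self.r2}")


def read_variant_table(path, kind: str) -> list[VariantRecord]:
    """Read a variant TSV (1-based positions). Columns: chrom, pos, plus
    var_id / variant_class / donor_id / study_id / partner_chrom /
    partner_pos where applicable."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(VariantRecord(
            chrom=normalize_chrom(d["chrom"]),
            position=int(d["pos"]) - 1,
            kind=kind,
            var_id=d.get("var_id", "") or "",
            variant_class=d.get("variant_class", "") or "",
            donor_id=d.get("donor_id", "") or "",
            study_id=d.get("study_id", "") or "",
            partner_chrom=normalize_chrom(d["partner_chrom"]) if d.get("partner_chrom") else "",
            partner_position=int(d["partner_pos"]) - 1 if d.get("partner_pos") else -1,
        ))
    return out


def read_ld_table(path) -> list[LdPair]:
    df = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str, "population": str})
    return [LdPair(r.rsid_a, r.rsid_b, float(r.r2), getattr(r, "population", ""))
            for r in df.itertuples(index=False)]


def ld_expand(snps: Sequence[VariantRecord], ld_pairs: Sequence[LdPair],
              snp_positions: Mapping[str, tuple[str, int]],
              r2_min: float = 0.8) -> list[VariantRecord]:
    """Add every SNP linked to a catalog SNP by r² strictly above ``r2_min``
    in at least one population; linked SNPs inherit the trait class.

    ``snp_positions`` maps rsid -> (chrom, 0-based position) for SNPs not in
    the catalog. Already-present SNPs are not duplicated.
    """
    by_id = {s.var_id: s for s in snps}
    linked: dict[str, set[str]] = {}
    for p in ld_pairs:
        if p.r2 > r2_min:
            linked.setdefault(p.snp_a, set()).add(p.snp_b)
            linked.setdefault(p.snp_b, set()).add(p.snp_a)
    out = list(snps)
    seen = set(by_id)
    for s in snps:
        for rsid in sorted(linked.get(s.var_id, ())):
            if rsid in seen or rsid not in snp_positions:
                continue
            chrom, pos = snp_positions[rsid]
            out.append(VariantRecord(normalize_chrom(chrom), pos, "GWAS_SNP", var_id=rsid,
                                     variant_class=s.variant_class, study_id=s.study_id))
            seen.add(rsid)
    return out


def variants_in(variants: Iterable[VariantRecord],
                elements: Sequence) -> list[VariantRecord]:
    """Variants whose position falls inside any of the (merged) elements."""
    merged = merge_overlapping(elements)
    index = IntervalIndex(merged)
    return [v for v in variants if index.any_overlap(v.chrom, v.position, v.position + 1)]


def density_per_kb(variants: Iterable[VariantRecord], elements: Sequence) -> float | None:
    """Variants per kb of merged element sequence; None for empty elements."""
    merged = merge_overlapping(elements)
    kb = total_bp(merged) / 1_000
    if kb == 0:
        return None
    return len(variants_in(variants, merged)) / kb


def class_fraction(variants_in_elements: Sequence[VariantRecord],
                   target_class: str) -> float | None:
    """Fraction of a target variant class among all variants in elements."""
    n = len(variants_in_elements)
    if n == 0:
        return None
    return sum(1 for v in variants_in_elements if v.variant_class == target_class) / n


def recurrent_fraction(variants: Sequence[VariantRecord], min_donors: int = 2) -> float:
    """Fraction of distinct variant positions observed in >= min_donors
    distinct donors."""
    donors: dict[tuple[str, int], set[str]] = {}
    for v in variants:
        donors.setdefault((v.chrom, v.position), set()).add(v.donor_id)
    if not donors:
        return 0.0
    rec = sum(1 for ds in donors.values() if len(ds) >= min_donors)
    return rec / len(donors)


def replicated_fraction(snps: Sequence[VariantRecord], trait_class: str,
                        min_studies: int = 2) -> float:
    """Fraction of trait-class SNPs reported by >= min_studies distinct
    studies of that trait class."""
    studies: dict[str, set[str]] = {}
    for s in snps:
        if s.variant_class == trait_class:
            studies.setdefault(s.var_id or f"{s.chrom}:{s.position}", set()).add(s.study_id)
    if not studies:
        return 0.0
    return sum(1 for st in studies.values() if len(st) >= min_studies) / len(studies)


def proximal_partition(variants: Sequence[VariantRecord], elements: Sequence,
                       flank: int = 50_000) -> list[str]:
    """Label each variant "in" (inside an element), "by" (within the +/-flank
    but not inside; boundary inclusive at exactly ``flank``), or "outside".
    Labels are exhaustive and exclusive; "in" takes precedence."""
    merged = merge_overlapping(elements)
    inside = IntervalIndex(merged)
    flanked = IntervalIndex(GenomicInterval(m.chrom, max(0, m.start - flank), m.end + flank)
                            for m in merged)
    labels = []
    for v in variants:
        if inside.any_overlap(v.chrom, v.position, v.position + 1):
            labels.append("in")
        elif flanked.any_overlap(v.chrom, v.position, v.position + 1):
            labels.append("by")
        else:
            labels.append("outside")
    return labels


_CLASS_PRECEDENCE = ("SS_component", "SE_component", "TS", "TE")


def _breakpoint_class(chrom: str, pos: int,
                      inside_idx: Mapping[str, IntervalIndex],
                      flank_idx: Mapping[str, IntervalIndex]) -> str:
    # precedence: in > by; among classes SS > SE > TS > TE > none
    for cls in _CLASS_PRECEDENCE:
        idx = inside_idx.get(cls)
        if idx is not None and idx.any_overlap(chrom, pos, pos + 1):
            return cls
    for cls in _CLASS_PRECEDENCE:
        idx = flank_idx.get(cls)
        if idx is not None and idx.any_overlap(chrom, pos, pos + 1):
            return cls
    return "none"


def translocation_partner_distribution(tlbps: Sequence[VariantRecord],
                                       elements_by_class: Mapping[str, Sequence],
                                       flank: int = 50_000) -> pd.DataFrame:
    """Count ordered (side A class, side B class) pairs of translocations.

    Each breakpoint is labeled by the element class it falls in or is
    proximal to (in > by; SS > SE > TS > TE > none).
    """
    inside_idx, flank_idx = {}, {}
    for cls, els in elements_by_class.items():
        merged = merge_overlapping(els)
        inside_idx[cls] = IntervalIndex(merged)
        flank_idx[cls] = IntervalIndex(
            GenomicInterval(m.chrom, max(0, m.start - flank), m.end + flank)
            for m in merged)
    counts: dict[tuple[str, str], int] = {}
    for t in tlbps:
        if t.kind != "TLBP":
            raise ValueError("translocation analysis requires TLBP records")
        a = _breakpoint_class(t.chrom, t.position, inside_idx, flank_idx)
        b = _breakpoint_class(t.partner_chrom, t.partner_position, inside_idx, flank_idx)
        counts[(a, b)] = counts.get((a, b), 0) + 1
    rows = [{"class_a": a, "class_b": b, "count": n}
            for (a, b), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["class_a", "class_b", "count"])


def binomial_enrichment(k: int, n: int, p0: float,
                        alternative: str = "two-sided") -> tuple[float, float] | None:
    """Fold enrichment (k/n)/p0 with an exact binomial p-value; None at n=0."""
    if not 0 < p0 < 1:
        raise ValueError(f"background rate must be in (0,1), got {p0}")
    if k < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if n == 0:
        return None
    fold = (k / n) / p0
    p = float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
    return fold, p
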