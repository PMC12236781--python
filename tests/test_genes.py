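"""Gene association: genomic context, nearest gene, contact genes, tau,
expression summaries, locus enrichment."""

import numpy as np
import pytest

from supersil.genes import (classify_genomic_context, contact_genes,
                            class_expression_summary, locus_enrichment,
                            nearest_gene, tau, GeneAssociation)
from supersil.intervals import Element, GenomicInterval
from supersil.io import Contact, ContactSet, GeneRecord


def el(start, end, name="", chrom="chr1"):
    return Element(GenomicInterval(chrom, start, end), name=name)


def gene(gid, tss, chrom="chr1", body=None, expression=None):
    body = body or (tss, tss + 10_000)
    return GeneRecord(gid, GenomicInterval(chrom, body[0], body[1]), tss,
                      expression=expression or {})


class TestGenomicContext:
    def test_element_containing_tss_is_promoter(self):
        assert classify_genomic_context(el(99_000, 101_000),
                                        [gene("G1", 100_000)]) == "promoter"

    def test_distant_element_is_intergenic(self):
        assert classify_genomic_context(el(5_000_000, 5_001_000),
                                        [gene("G1", 100_000)]) == "intergenic"

    def test_gene_body_without_promoter_is_intragenic(self):
        g = gene("G1", 100_000, body=(100_000, 200_000))
        assert classify_genomic_context(el(150_000, 151_000), [g]) == "intragenic"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(67)
        genes = [gene(f"G{i}", int(t), body=(int(t), int(t) + 20_000))
                 for i, t in enumerate(rng.integers(0, 900_000, 15))]
        flank = 2_000
        for _ in range(100):
            s = int(rng.integers(0, 950_000))
            e = el(s, s + 1_000)
            if any(e.start < g.tss + flank and e.end > g.tss - flank for g in genes):
                expected = "promoter"
            elif any(e.start < g.body.end and e.end > g.body.start for g in genes):
                expected = "intragenic"
            else:
                expected = "intergenic"
            assert classify_genomic_context(e, genes, flank) == expected


class TestNearestGene:
    def test_element_containing_tss(self):
        a = nearest_gene(el(99_500, 100_500), [gene("G1", 100_000)])
        assert a.gene_id == "G1" and a.distance == 0

    def test_equidistant_tie_smaller_id(self):
        gs = [gene("B", 90_000), gene("A", 110_000)]
        assert nearest_gene(el(99_500, 100_500), gs).gene_id == "A"

    def test_empty_chromosome_missing(self):
        assert nearest_gene(el(0, 1000, chrom="chr9"), [gene("G1", 5_000)]) is None

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(71)
        genes = [gene(f"G{i:02d}", int(t)) for i, t in
                 enumerate(rng.integers(0, 1_000_000, 30))]
        for _ in range(100):
            s = int(rng.integers(0, 999_000))
            e = el(s, s + 1_000)
            mid = (e.start + e.end) // 2
            expected = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
            assert nearest_gene(e, genes).gene_id == expected.gene_id


class TestContactGenes:
    def _contacts(self, pairs):
        cs = ContactSet(min_span=80_000)
        for (s1, e1), (s2, e2) in pairs:
            cs.add(Contact("chr1", s1, e1, "chr1", s2, e2))
        return cs

    def test_no_contacts_empty(self):
        assert contact_genes(el(0, 1000), self._contacts([]), [gene("G1", 500_000)]) == {}

    def test_single_element_promoter_contact(self):
        cs = self._contacts([((0, 10_000), (499_000, 509_000))])
        got = contact_genes(el(500, 1_500), cs, [gene("G1", 500_000)])
        assert got == {"G1": 1}

    def test_matches_brute_force_anchor_overlap(self):
        rng = np.random.default_rng(73)
        genes = [gene(f"G{i}", int(t)) for i, t in
                 enumerate(np.sort(rng.integers(0, 2_000_000, 20)))]
        e = el(1_000_000, 1_001_500)
        cs = ContactSet(min_span=80_000)
        for _ in range(60):
            a = int(rng.integers(0, 1_990_000) // 10_000 * 10_000)
            b = int(rng.integers(0, 1_990_000) // 10_000 * 10_000)
            if abs(b - a) >= 90_000:
                cs.add(Contact("chr1", min(a, b), min(a, b) + 10_000,
                               "chr1", max(a, b), max(a, b) + 10_000))
        flank = 2_000
        expected = {}
        for c in cs:
            for (a1, a2, b1, b2) in [(c.start1, c.end1, c.start2, c.end2),
                                     (c.start2, c.end2, c.start1, c.end1)]:
                if a1 < e.end and a2 > e.start:
                    for g in genes:
                        if b1 < g.tss + flank and b2 > g.tss - flank:
                            expected[g.gene_id] = expected.get(g.gene_id, 0) + 1
        assert contact_genes(e, cs, genes, flank) == expected


class TestTau:
    def test_uniform_expression_zero(self):
        assert tau([3.0, 3.0, 3.0, 3.0]) == pytest.approx(0.0)

    def test_single_cell_type_one(self):
        assert tau([0.0, 0.0, 5.0, 0.0]) == pytest.approx(1.0)

    def test_two_type_example(self):
        assert tau([1.0, 0.5]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(79)
        for _ in range(100):
            x = rng.uniform(0, 10, 8)
            assert tau(x) == pytest.approx(tau(17.3 * x))

    def test_all_zero_missing(self):
        assert tau([0.0, 0.0]) is None

    def test_negative_inputs_shifted(self):
        # log-scale input: shifting by the minimum keeps tau in [0, 1]
        v = tau([-2.0, -1.0, 3.0])
        assert 0.0 <= v <= 1.0

    def test_requires_two_cell_types(self):
        with pytest.raises(ValueError):
            tau([1.0])


class TestClassExpressionSummary:
    def test_identical_expression_gives_unit_ratios(self):
        expr = {f"G{i}": {"c1": 2.0, "c2": 2.0} for i in range(6)}
        assoc = {
            "SS_component": [GeneAssociation("e1", "G0", "proximal"),
                             GeneAssociation("e2", "G1", "proximal")],
            "TS": [GeneAssociation("e3", "G2", "proximal"),
                   GeneAssociation("e4", "G3", "proximal")],
        }
        df = class_expression_summary(assoc, expr)
        ss = df[df.element_class == "SS_component"]
        assert (ss.ratio_vs_reference == 1.0).all()

    def test_single_gene_class_summary_is_that_value(self):
        expr = {"G0": {"c1": 7.0}, "G1": {"c1": 1.0}}
        assoc = {"SS_component": [GeneAssociation("e1", "G0", "proximal")],
                 "TS": [GeneAssociation("e2", "G1", "proximal")]}
        df = class_expression_summary(assoc, expr)
        row = df[(df.element_class == "SS_component") & (df.cell_type == "c1")].iloc[0]
        assert row["mean"] == row["median"] == 7.0
        assert row.ratio_vs_reference == 7.0


class TestLocusEnrichment:
    def _setup(self):
        loci = {"essential": [GenomicInterval("chr1", 1_000_000, 1_020_000)]}
        inside = [el(1_000_000 + 2_000 * i, 1_000_000 + 2_000 * i + 500) for i in range(4)]
        outside = [el(5_000_000 + 10_000 * i, 5_000_000 + 10_000 * i + 500)
                   for i in range(4)]
        return loci, inside, outside

    def test_all_in_loci_with_half_background(self):
        loci, inside, outside = self._setup()
        background = inside[:2] + outside[:2]  # background fraction 0.5
        df = locus_enrichment({"SS_component": inside}, loci, background)
        assert df.iloc[0].fold == pytest.approx(2.0)

    def test_no_class_elements_in_loci(self):
        loci, inside, outside = self._setup()
        df = locus_enrichment({"TS": outside}, loci, inside)
        assert df.iloc[0].fold == 0.0

    def test_zero_background_fraction_missing(self):
        loci, inside, outside = self._setup()
        df = locus_enrichment({"SS_component": inside}, loci, outside)
        assert np.isnan(df.iloc[0].fold)

    def test_background_like_class_gives_unit_fold(self):
        rng = np.random.default_rng(83)
        loci = {"set": [GenomicInterval("chr1", 0, 2_000_000)]}
        elements = [el(int(s), int(s) + 500) for s in rng.integers(0, 10_000_000, 400)]
        df = locus_enrichment({"X": elements}, loci, elements, flank=0)
        assert df.iloc[0].fold == pytest.approx(1.0)
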