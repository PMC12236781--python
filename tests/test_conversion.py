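"""Silencer/enhancer conversion detection, recurrence, expression response,
and contact retention."""

import numpy as np
import pandas as pd
import pytest

from supersil.conversion import (ConversionRecord, associated_gene_fold_change,
                                 contact_retention, detect_conversions,
                                 recurrence, response_fractions)
from supersil.intervals import Element, GenomicInterval
from supersil.io import Contact, ContactSet


def el(start, end, cls="SS_component", name="", chrom="chr1"):
    return Element(GenomicInterval(chrom, start, end), element_class=cls, name=name)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestDetectConversions:
    def test_no_overlap_no_record(self):
        samples = {"s1": [iv(500_000, 600_000)]}
        assert detect_conversions([el(0, 1_000)], samples) == []

    def test_supporters_counted_across_samples(self):
        src = el(10_000, 11_500)
        samples = {f"s{i}": ([iv(10_000, 50_000)] if i < 3 else [iv(900_000, 950_000)])
                   for i in range(6)}
        (rec,) = detect_conversions([src], samples)
        assert rec.direction == "SS_to_SE"
        assert len(rec.supporting_samples) == 3 and rec.n_samples == 6

    def test_direction_labels_follow_source_class(self):
        samples = {"s1": [iv(0, 100_000)]}
        for cls, direction in [("SS_component", "SS_to_SE"), ("TS", "TS_to_SE"),
                               ("TE", "TE_to_SE"), ("SE_component", "SE_to_SS")]:
            (rec,) = detect_conversions([el(10, 1_000, cls)], samples)
            assert rec.direction == direction

    def test_matches_brute_force_per_sample_overlap(self):
        rng = np.random.default_rng(107)
        sources = [el(int(s), int(s) + 1_500, name=f"e{i}")
                   for i, s in enumerate(rng.integers(0, 900_000, 40))]
        samples = {}
        for si in range(5):
            samples[f"s{si}"] = [iv(int(a), int(a) + int(rng.integers(5_000, 40_000)))
                                 for a in rng.integers(0, 900_000, 10)]
        records = {r.source.name: set(r.supporting_samples)
                   for r in detect_conversions(sources, samples)}
        for src in sources:
            expected = {sid for sid, regions in samples.items()
                        if any(src.start < r.end and src.end > r.start for r in regions)}
            assert records.get(src.name, set()) == expected


class TestRecurrence:
    @pytest.mark.parametrize("supporters, total, expected", [
        (4, 6, True),
        (3, 6, False),   # strict majority required
        (5, 8, True),
        (4, 8, False),
    ])
    def test_strict_majority(self, supporters, total, expected):
        rec = ConversionRecord(el(0, 1_000), "SS_to_SE",
                               tuple(f"s{i}" for i in range(supporters)), total)
        flag, frac = recurrence(rec)
        assert flag is expected
        assert frac == pytest.approx(supporters / total)


class TestFoldChange:
    def _rec(self, gene):
        return ConversionRecord(el(0, 1_000), "SS_to_SE", ("s1",), 2,
                                associated_gene=gene)

    def test_equal_expression_unit_fold(self):
        df = associated_gene_fold_change([self._rec("G1")], {"G1": 5.0}, {"G1": 5.0})
        assert df.iloc[0].fold == pytest.approx(1.0)

    def test_pseudocount_example(self):
        df = associated_gene_fold_change([self._rec("G1")], {"G1": 1.0}, {"G1": 10.0})
        assert df.iloc[0].fold == pytest.approx(5.5)  # (10+1)/(1+1)

    def test_double_zero_unit_fold(self):
        df = associated_gene_fold_change([self._rec("G1")], {"G1": 0.0}, {"G1": 0.0})
        assert df.iloc[0].fold == pytest.approx(1.0)

    def test_missing_expression_skipped_and_counted(self):
        df = associated_gene_fold_change([self._rec("G1"), self._rec("G9")],
                                         {"G1": 1.0}, {"G1": 2.0})
        assert len(df) == 1
        assert df.attrs["n_skipped_missing_expression"] == 1


class TestResponseFractions:
    def _timecourse(self, genes, shift_genes=(), shift=-5.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in genes:
            for tp in (2, 6):
                for cond in ("control", "treated"):
                    for rep in range(3):
                        v = 10.0 + (shift if cond == "treated" and g in shift_genes else 0.0)
                        rows.append({"gene": g, "timepoint": tp, "condition": cond,
                                     "replicate": rep,
                                     "value": v + float(rng.normal(0, noise)) if noise else v})
        return pd.DataFrame(rows)

    def test_identical_replicates_no_significance(self):
        tc = self._timecourse(["G1", "G2"])
        df = response_fractions(tc, {"G1": "X", "G2": "X"})
        assert (df.frac_down == 0).all() and (df.frac_up == 0).all()

    def test_planted_downshift_only_in_target_class(self):
        genes = [f"G{i}" for i in range(12)]
        tc = self._timecourse(genes, shift_genes=genes[:4], noise=0.3, seed=3)
        classes = {g: ("hit" if g in genes[:4] else "other") for g in genes}
        df = response_fractions(tc, classes)
        hit_down = df[df.gene_class == "hit"].frac_down.mean()
        other_down = df[df.gene_class == "other"].frac_down.mean()
        assert hit_down > 0.9 > other_down + 0.5

    def test_alpha_one_counts_every_gene(self):
        tc = self._timecourse(["G1"], shift_genes=["G1"], noise=0.3, seed=5)
        df = response_fractions(tc, {"G1": "X"}, alpha=1.0)
        assert ((df.frac_down + df.frac_up) == 1.0).all()

    def test_single_replicate_errors_with_gene_name(self):
        tc = self._timecourse(["G1"])
        tc = tc[~((tc.condition == "treated") & (tc.replicate > 0))]
        with pytest.raises(ValueError, match="G1"):
            response_fractions(tc, {"G1": "X"})


class TestContactRetention:
    def _contacts(self, pairs):
        cs = ContactSet(min_span=80_000)
        for a, b in pairs:
            cs.add(Contact("chr1", a, a + 10_000, "chr1", b, b + 10_000))
        return cs

    def test_identical_sets_fully_retained(self):
        pairs = [(0, 100_000), (50_000, 200_000)]
        cs = self._contacts(pairs)
        anchors = {"SS_component": [el(0, 5_000)]}
        df = contact_retention(cs, self._contacts(pairs), anchors)
        assert df.iloc[0].retained_fraction == 1.0

    def test_disjoint_sets_zero(self):
        cs = self._contacts([(0, 100_000)])
        other = self._contacts([(500_000, 700_000)])
        df = contact_retention(cs, other, {"SS_component": [el(0, 5_000)]})
        assert df.iloc[0].retained_fraction == 0.0

    def test_random_half_subsample_near_half(self):
        rng = np.random.default_rng(109)
        pairs = [(int(a) * 10_000, int(a) * 10_000 + 200_000)
                 for a in rng.integers(0, 100, 200)]
        pairs = sorted(set(pairs))
        keep = [p for p in pairs if rng.random() < 0.5]
        ref = self._contacts(pairs)
        other = self._contacts(keep)
        anchors = {"X": [el(0, 1_200_000)]}
        df = contact_retention(ref, other, anchors)
        assert df.iloc[0].retained_fraction == pytest.approx(len(keep) / len(pairs),
                                                             abs=0.1)

    def test_bin_size_mismatch_errors(self):
        a = ContactSet(bin_size=10_000)
        b = ContactSet(bin_size=5_000)
        with pytest.raises(ValueError, match="bin size"):
            contact_retention(a, b, {"X": []})
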