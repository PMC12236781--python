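"""Activity encoding, cosine cooperativity, Jaccard TFBS similarity,
distance-matched background sampling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from supersil.cooperativity import (build_activity_matrix, build_tfbs_matrix,
                                    cooperativity, encode_activity,
                                    fraction_tfs_multibound,
                                    matched_background_pairs, pair_distance,
                                    region_pair_scores, tfbs_similarity)
from supersil.intervals import Element, GenomicInterval, IntervalIndex
from supersil.supercall import SuperRegion


def el(start, end, name="", chrom="chr1"):
    return Element(GenomicInterval(chrom, start, end), name=name)


def region(members):
    iv = GenomicInterval(members[0].chrom, members[0].start, members[-1].end)
    return SuperRegion(interval=iv, members=list(members))


class TestEncodeActivity:
    @pytest.mark.parametrize("has_ac, has_me, expected", [
        (False, True, -1),   # repressive mark only
        (True, False, 1),    # active mark only
        (True, True, 0),     # both marks: uncertain
        (False, False, 0),   # neither mark
    ])
    def test_four_cases(self, has_ac, has_me, expected):
        e = el(100, 200)
        ac = IntervalIndex([GenomicInterval("chr1", 150, 160)]) if has_ac else IntervalIndex([])
        me = IntervalIndex([GenomicInterval("chr1", 150, 160)]) if has_me else IntervalIndex([])
        assert encode_activity(e, ac, me) == expected

    def test_matrix_entries_bounded(self):
        els = [el(0, 100, "a"), el(200, 300, "b")]
        m = build_activity_matrix(
            els, {"c1": [GenomicInterval("chr1", 0, 50)]},
            {"c1": [GenomicInterval("chr1", 250, 260)], "c2": []})
        assert set(np.unique(m.to_numpy())) <= {-1, 0, 1}
        assert m.loc["a", "c1"] == 1 and m.loc["b", "c1"] == -1


class TestCooperativity:
    def test_identical_rows(self):
        assert cooperativity([1, 1, -1], [1, 1, -1]) == pytest.approx(1.0)

    def test_opposite_rows(self):
        assert cooperativity([1, 1], [-1, -1]) == pytest.approx(-1.0)

    def test_orthogonal_rows(self):
        assert cooperativity([1, -1, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_all_zero_row_is_missing(self):
        assert cooperativity([0, 0, 0], [1, 1, 0]) is None

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            cooperativity([1, 0], [1, 0, -1])

    def test_matches_generic_cosine_oracle(self):
        rng = np.random.default_rng(53)
        for _ in range(500):
            a = rng.integers(-1, 2, 20)
            b = rng.integers(-1, 2, 20)
            got = cooperativity(a, b)
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                assert got is None
            else:
                assert got == pytest.approx(float(np.dot(a, b)) / (na * nb))
                assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12
                assert got == pytest.approx(cooperativity(b, a))


class TestTfbsSimilarity:
    def test_identical_nonempty(self):
        assert tfbs_similarity([1, 0, 1], [1, 0, 1]) == pytest.approx(1.0)

    def test_disjoint(self):
        assert tfbs_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_one_of_three(self):
        # rows {A,B} and {B,C}: |intersection| / |union| = 1/3
        assert tfbs_similarity([1, 1, 0], [0, 1, 1]) == pytest.approx(1 / 3)

    def test_both_empty_is_missing(self):
        assert tfbs_similarity([0, 0], [0, 0]) is None

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(59)
        for _ in range(500):
            a = rng.integers(0, 2, 15)
            b = rng.integers(0, 2, 15)
            sa = {i for i, v in enumerate(a) if v}
            sb = {i for i, v in enumerate(b) if v}
            got = tfbs_similarity(a, b)
            if not sa and not sb:
                assert got is None
            else:
                assert got == pytest.approx(len(sa & sb) / len(sa | sb))


class TestRegionPairScores:
    def _matrix(self, names):
        return pd.DataFrame([[1, -1, 0]] * len(names), index=names,
                            columns=["c1", "c2", "c3"])

    def test_pair_counts(self):
        two = region([el(0, 100, "a"), el(200, 300, "b")])
        five = region([el(1000 * i, 1000 * i + 100, f"m{i}") for i in range(5)])
        assert len(region_pair_scores(two, self._matrix(["a", "b"]))) == 1
        assert len(region_pair_scores(five, self._matrix([f"m{i}" for i in range(5)]))) == 10

    def test_single_member_region_empty(self):
        one = region([el(0, 100, "a")])
        assert region_pair_scores(one, self._matrix(["a"])) == []


class TestMatchedBackground:
    def test_pool_equals_components_matches_exactly(self):
        els = [el(10_000 * i, 10_000 * i + 1000, f"e{i}") for i in range(6)]
        pairs = list(itertools.combinations(els, 2))
        bg, kept = matched_background_pairs(pairs, els, seed=0)
        target = sorted(pair_distance(a, b) for a, b in kept)
        got = sorted(pair_distance(a, b) for a, b in bg)
        assert got == target
        assert len(kept) == len(pairs)

    def test_deterministic_per_seed(self):
        els = [el(7_000 * i, 7_000 * i + 500, f"e{i}") for i in range(10)]
        pairs = list(itertools.combinations(els[:4], 2))
        bg1, _ = matched_background_pairs(pairs, els, seed=5)
        bg2, _ = matched_background_pairs(pairs, els, seed=5)
        assert [(a.name, b.name) for a, b in bg1] == [(a.name, b.name) for a, b in bg2]

    def test_unfillable_bin_dropped_from_both_sides(self):
        close = [el(0, 1000, "a"), el(2_000, 3_000, "b")]  # 2 kb apart
        far_pool = [el(0, 1000, "x"), el(500_000, 501_000, "y")]
        with pytest.warns(UserWarning, match="unfillable"):
            bg, kept = matched_background_pairs([(close[0], close[1])], far_pool, seed=0)
        assert bg == [] and kept == []

    def test_histograms_equal_per_bin(self):
        rng = np.random.default_rng(61)
        pool = [el(int(s), int(s) + 500, f"p{i}")
                for i, s in enumerate(np.sort(rng.integers(0, 2_000_000, 120)))]
        fg = list(itertools.combinations(pool[:15], 2))
        bg, kept = matched_background_pairs(fg, pool, seed=3)
        bins = np.array([0, 1e3, 4e3, 16e3, 64e3, 256e3, 1_048_576, np.inf])
        h_bg, _ = np.histogram([pair_distance(a, b) for a, b in bg], bins=bins)
        h_fg, _ = np.histogram([pair_distance(a, b) for a, b in kept], bins=bins)
        assert np.array_equal(h_bg, h_fg)


class TestFractionTfsMultibound:
    def _tfbs(self, rows, names, tfs):
        return pd.DataFrame(rows, index=names, columns=tfs)

    def test_no_binding(self):
        r = region([el(0, 100, "a"), el(200, 300, "b")])
        m = self._tfbs([[0, 0], [0, 0]], ["a", "b"], ["TF1", "TF2"])
        assert fraction_tfs_multibound(r, m) == 0.0

    def test_one_of_four_tfs_in_two_members(self):
        r = region([el(0, 100, "a"), el(200, 300, "b"), el(400, 500, "c")])
        rows = [[1, 0, 0, 0], [1, 0, 1, 0], [0, 0, 0, 0]]
        m = self._tfbs(rows, ["a", "b", "c"], ["T1", "T2", "T3", "T4"])
        assert fraction_tfs_multibound(r, m) == 0.25

    def test_every_tf_everywhere(self):
        r = region([el(0, 100, "a"), el(200, 300, "b")])
        m = self._tfbs([[1, 1], [1, 1]], ["a", "b"], ["T1", "T2"])
        assert fraction_tfs_multibound(r, m) == 1.0


def test_tfbs_matrix_from_peak_occupancy():
    els = [el(0, 1000, "a"), el(5000, 6000, "b")]
    peaks = {"TF1": [GenomicInterval("chr1", 100, 200)],
             "TF2": [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5500, 5600)]}
    m = build_tfbs_matrix(els, peaks)
    assert m.loc["a"].tolist() == [1, 1]
    assert m.loc["b"].tolist() == [0, 1]
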