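"""Interval analytics: promoter windows, assignment, classification,
k-way intersection (with per-base-pair oracle), permutation null, TSS
coverage, Venn counts."""

import dataclasses

import numpy as np
import pytest

from prognet.core import GeneModel, GenomicInterval, PeakSet
from prognet.peaks import (
    assign_peaks_to_genes,
    classify_peaks,
    gene_set_overlaps,
    multiway_intersection,
    permutation_overlap_test,
    promoter_windows,
    tss_coverage_matrix,
)
from prognet.simulate import gen_genome_peaks


def _ps(name, triples):
    return PeakSet(name, [GenomicInterval(c, s, e) for c, s, e in triples])


def bp_oracle_intersection(peaksets, genome_len, chrom="chr1"):
    """Per-base-pair boolean AND oracle: merged regions covered by all sets."""
    covered = np.ones(genome_len, dtype=bool)
    for ps in peaksets:
        mask = np.zeros(genome_len, dtype=bool)
        for iv in ps.intervals:
            if iv.chrom == chrom:
                mask[iv.start:iv.end] = True
        covered &= mask
    # extract maximal runs
    padded = np.concatenate([[False], covered, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


class TestPromoterWindows:
    def test_plus_strand_window(self):
        g = GeneModel("G1", "chr1", "+", 10_000)
        w = promoter_windows([g])[0]
        assert (w.start, w.end) == (8000, 12_500)

    def test_minus_strand_window_is_reflected(self):
        g = GeneModel("G1", "chr1", "-", 10_000)
        w = promoter_windows([g])[0]
        assert (w.start, w.end) == (7500, 12_000)

    def test_clipping_at_chromosome_bounds(self):
        g = GeneModel("G1", "chr1", "+", 500)
        w = promoter_windows([g], chrom_sizes={"chr1": 2800})[0]
        assert (w.start, w.end) == (0, 2800)


class TestAssignPeaks:
    def test_single_bp_overlap_counts(self):
        g = GeneModel("G1", "chr1", "+", 10_000)  # window [8000, 12500)
        windows = promoter_windows([g])
        pos, hits = assign_peaks_to_genes(_ps("T", [("chr1", 7900, 8001)]), windows)
        assert pos == {"G1"}
        assert len(hits["G1"]) == 1

    def test_abutting_peak_is_negative(self):
        g = GeneModel("G1", "chr1", "+", 10_000)
        windows = promoter_windows([g])
        pos, _ = assign_peaks_to_genes(_ps("T", [("chr1", 7000, 8000)]), windows)
        assert pos == set()

    def test_planted_cobound_genes_recovered(self, small_config):
        genome = gen_genome_peaks(small_config)
        windows = promoter_windows(genome["genes"], chrom_sizes=genome["chrom_sizes"])
        sets = [assign_peaks_to_genes(ps, windows)[0] for ps in genome["peaksets"]]
        four_way = set.intersection(*sets)
        assert set(genome["truth"]["cobound_genes"]) <= four_way


class TestClassifyPeaks:
    @staticmethod
    def _gene(tss=50_000):
        # + strand gene: exons [tss, tss+500) and [tss+8000, tss+9000);
        # the intron reaches past the promoter window (ends at tss+2500)
        return GeneModel(
            "G1", "chr1", "+", tss,
            [GenomicInterval("chr1", tss, tss + 500),
             GenomicInterval("chr1", tss + 8000, tss + 9000)],
        )

    def test_priority_promoter_beats_exon(self):
        g = self._gene()
        peaks = _ps("T", [("chr1", g.tss + 100, g.tss + 300)])  # promoter & exon
        cats, _ = classify_peaks(peaks, [g], _ps("m1", []), _ps("m2", []))
        assert cats == ["promoter"]

    def test_intron_between_exons(self):
        g = self._gene()
        peaks = _ps("T", [("chr1", g.tss + 3500, g.tss + 3900)])
        cats, _ = classify_peaks(peaks, [g], _ps("m1", []), _ps("m2", []))
        assert cats == ["intron"]

    def test_enhancer_rules(self):
        g = self._gene()
        far = 200_000
        peaks = _ps("T", [(("chr1"), far, far + 400), ((("chr1")), far + 10_000, far + 10_400)])
        m1 = _ps("m1", [("chr1", far - 100, far + 500),
                        ("chr1", far + 9_900, far + 10_500)])
        m2 = _ps("m2", [("chr1", far - 100, far + 500)])
        cats, counts = classify_peaks(peaks, [g], m1, m2)
        assert cats == ["active_enhancer", "enhancer"]
        assert sum(counts.values()) == 2

    def test_mark2_alone_rule(self):
        g = self._gene()
        far = 200_000
        peaks = _ps("T", [("chr1", far, far + 400)])
        m1 = _ps("m1", [])
        m2 = _ps("m2", [("chr1", far, far + 400)])
        cats_both, _ = classify_peaks(peaks, [g], m1, m2)
        cats_m2, _ = classify_peaks(peaks, [g], m1, m2, active_enhancer_rule="mark2")
        assert cats_both == ["intergenic"]
        assert cats_m2 == ["active_enhancer"]

    def test_partition_property_on_synthetic_genome(self, small_config):
        genome = gen_genome_peaks(small_config)
        for ps in genome["peaksets"]:
            cats, counts = classify_peaks(
                ps, genome["genes"], genome["mark1"], genome["mark2"],
                chrom_sizes=genome["chrom_sizes"],
            )
            assert len(cats) == len(ps)
            assert sum(counts.values()) == len(ps)


class TestMultiwayIntersection:
    def test_four_set_hand_example(self):
        sets = [
            _ps("A", [("chr1", 0, 100)]),
            _ps("B", [("chr1", 50, 150)]),
            _ps("C", [("chr1", 60, 70)]),
            _ps("D", [("chr1", 65, 200)]),
        ]
        out = multiway_intersection(sets)
        assert [(iv.start, iv.end) for iv in out] == [(65, 70)]

    def test_empty_input_set_gives_empty_result(self):
        sets = [_ps("A", [("chr1", 0, 100)]), _ps("B", [])]
        assert multiway_intersection(sets) == []

    def test_self_intersection_is_merged_self(self):
        ps = _ps("A", [("chr1", 0, 50), ("chr1", 40, 100), ("chr1", 200, 300)])
        out = multiway_intersection([ps, ps])
        assert [(iv.start, iv.end) for iv in out] == [(0, 100), (200, 300)]

    def test_no_input_rejected(self):
        with pytest.raises(ValueError):
            multiway_intersection([])

    def test_matches_per_bp_oracle_on_random_genomes(self, rng):
        genome_len = 10_000
        for _ in range(25):
            k = int(rng.integers(2, 5))
            sets = []
            for i in range(k):
                n_peaks = int(rng.integers(5, 40))
                starts = rng.integers(0, genome_len - 200, n_peaks)
                lens = rng.integers(1, 200, n_peaks)
                sets.append(
                    _ps(f"S{i}", [("chr1", int(s), int(min(genome_len, s + l)))
                                  for s, l in zip(starts, lens)])
                )
            expected = bp_oracle_intersection(sets, genome_len)
            got = [(iv.start, iv.end) for iv in multiway_intersection(sets)]
            assert got == expected


class TestPermutationTest:
    def test_identical_sets_give_minimal_p(self, rng):
        starts = rng.integers(0, 90_000, 40)
        ivs = [("chr1", int(s), int(s) + 300) for s in starts]
        sets = [_ps(n, ivs) for n in "ABCD"]
        res = permutation_overlap_test(sets, {"chr1": 100_000}, n_perm=999, seed=5)
        assert res.p_empirical == pytest.approx(1 / 1000)

    def test_zero_permutations_rejected(self):
        sets = [_ps("A", [("chr1", 0, 10)])] * 2
        with pytest.raises(ValueError):
            permutation_overlap_test(sets, {"chr1": 100}, n_perm=0)

    def test_oversized_peak_rejected(self):
        sets = [_ps("A", [("chr1", 0, 10)]), _ps("B", [("chr1", 0, 90)])]
        with pytest.raises(ValueError, match="exceeds"):
            permutation_overlap_test(sets, {"chr1": 50}, n_perm=10)

    def test_circular_null_preserves_total_coverage(self, rng):
        starts = rng.integers(0, 9000, 20)
        sets = [
            _ps("A", [("chr1", int(s), int(s) + 100) for s in starts]),
            _ps("B", [("chr1", int(s), int(s) + 100) for s in starts]),
        ]
        res = permutation_overlap_test(
            sets, {"chr1": 10_000}, n_perm=20, seed=3, null="circular"
        )
        assert res.observed >= 1
        assert res.n_perm == 20


class TestTssCoverage:
    def test_single_peak_fills_exactly_one_bin(self):
        g = GeneModel("G1", "chr1", "+", 50_000)
        # bin 0 spans [40000, 40100): place a peak covering it exactly
        peaks = _ps("T", [("chr1", 40_000, 40_100)])
        order, mat = tss_coverage_matrix(peaks, [g], bin_size=100)
        assert order == ["G1"]
        assert mat[0, 0] == 100
        assert mat[0, 1:].sum() == 0

    def test_no_peaks_zero_matrix(self):
        g = GeneModel("G1", "chr1", "+", 50_000)
        _, mat = tss_coverage_matrix(_ps("T", []), [g])
        assert not mat.any()

    def test_minus_strand_reversal_preserves_row_sum(self, rng):
        peaks = _ps("T", [("chr1", int(s), int(s) + 500)
                          for s in rng.integers(40_000, 60_000, 10)])
        g_plus = GeneModel("G1", "chr1", "+", 50_000)
        g_minus = GeneModel("G1", "chr1", "-", 50_000)
        _, mat_p = tss_coverage_matrix(peaks, [g_plus])
        _, mat_m = tss_coverage_matrix(peaks, [g_minus])
        assert mat_p.sum() == pytest.approx(mat_m.sum())
        np.testing.assert_allclose(mat_m[0], mat_p[0][::-1])

    def test_rows_ordered_by_ranking_factor_score(self):
        genes = [GeneModel("Glow", "chr1", "+", 50_000),
                 GeneModel("Ghigh", "chr1", "+", 150_000)]
        peaks = PeakSet("T", [
            GenomicInterval("chr1", 49_000, 49_400, ".", 5.0),
            GenomicInterval("chr1", 149_000, 149_400, ".", 50.0),
        ])
        order, _ = tss_coverage_matrix(peaks, genes, use_score=False)
        assert order == ["Ghigh", "Glow"]


class TestGeneSetOverlaps:
    def test_identical_sets_concentrate_in_full_region(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        counts = gene_set_overlaps(sets)
        assert counts == {frozenset({"A", "B"}): 2}

    def test_disjoint_sets_only_singletons(self):
        counts = gene_set_overlaps({"A": {"g1"}, "B": {"g2"}})
        assert counts == {frozenset({"A"}): 1, frozenset({"B"}): 1}

    def test_matches_brute_force_and_sums_to_union(self, rng):
        names = ["A", "B", "C", "D"]
        universe = [f"g{i}" for i in range(60)]
        sets = {
            n: set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for n in names
        }
        counts = gene_set_overlaps(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))
        for member, c in counts.items():
            brute = sum(
                1 for g in universe
                if all((g in sets[n]) == (n in member) for n in names)
            )
            assert c == brute
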