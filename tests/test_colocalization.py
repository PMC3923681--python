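import numpy as np
import pytest

from cohesichip.colocalization import (SignalMatrix, coloc_score,
                                       conservation, nearest_peak_distances,
                                       peak_overlap, signal_profile,
                                       top_n_heatmap)
from cohesichip.formats_io import AlignedRead
from conftest import make_peak, random_peaks
from oracles import oracle_nearest, oracle_overlap_mask


def read_at(chrom, pos, n_hits=1, rid="r"):
    return AlignedRead(chrom, pos, "+", n_hits, read_id=rid)


class TestSignalProfile:
    def test_single_read_lands_in_its_bin(self):
        pk = make_peak("chr1", 900, 1100, 1000)
        mat = signal_profile([pk], [read_at("chr1", 1037)], flank=200,
                             bin_size=10, total_reads=1e6)
        nz = np.nonzero(mat.values)
        assert list(zip(*nz)) == [(0, 23)]  # offset 37 -> bin [30, 40)
        assert mat.values[0, 23] == pytest.approx(1e7 / 1e6)

    def test_zero_reads_gives_zero_matrix(self):
        pk = make_peak("chr1", 900, 1100, 1000)
        mat = signal_profile([pk], [], flank=200, bin_size=10, total_reads=10)
        assert not mat.values.any()

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            signal_profile([make_peak("chr1", 0, 100)], [], flank=200,
                           bin_size=30, total_reads=1)

    def test_rows_ordered_by_score_strongest_last(self):
        peaks = [make_peak("chr1", i * 1000, i * 1000 + 100, score=s,
                           name=f"p{s}")
                 for i, s in enumerate([5.0, 1.0, 3.0])]
        mat = signal_profile(peaks, [], flank=100, bin_size=10, total_reads=1)
        assert mat.peak_names == ["p1.0", "p3.0", "p5.0"]

    def test_mass_conservation(self):
        rng = np.random.default_rng(0)
        peaks = random_peaks(rng, 20, span=50_000)
        reads = [read_at("chr1", int(rng.integers(0, 50_000)),
                         int(rng.integers(1, 5)), f"r{i}")
                 for i in range(2000)]
        mat = signal_profile(peaks, reads, flank=200, bin_size=10)
        for row, name in enumerate(mat.peak_names):
            pk = next(p for p in peaks if p.name == name)
            expect = sum(r.weight for r in reads
                         if r.chrom == pk.chrom
                         and pk.summit - 200 <= r.five_prime_pos
                         < pk.summit + 200)
            got = mat.values[row].sum() * mat.total_reads / 1e7
            assert got == pytest.approx(expect)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        peaks = random_peaks(rng, 10, chroms=("chr1",), span=50_000)
        reads = [read_at("chr1", int(rng.integers(0, 50_000)), 1, f"r{i}")
                 for i in range(500)]
        shift = 7919
        peaks2 = [make_peak(p.chrom, p.interval.start + shift,
                            p.interval.end + shift, p.summit + shift,
                            p.score, p.name) for p in peaks]
        reads2 = [read_at(r.chrom, r.five_prime_pos + shift, 1, r.read_id)
                  for r in reads]
        m1 = signal_profile(peaks, reads, 200, 10)
        m2 = signal_profile(peaks2, reads2, 200, 10)
        np.testing.assert_array_equal(m1.values, m2.values)


class TestTopN:
    def _world(self):
        rng = np.random.default_rng(2)
        peaks = random_peaks(rng, 15, span=50_000)
        reads = [read_at("chr1", int(rng.integers(0, 50_000)), 1, f"r{i}")
                 for i in range(300)]
        return peaks, reads

    def test_n_equals_all_matches_signal_profile(self):
        peaks, reads = self._world()
        full = signal_profile(peaks, reads, 200, 10)
        top = top_n_heatmap(peaks, reads, len(peaks), 200, 10)
        np.testing.assert_array_equal(full.values, top.values)

    def test_n_one_is_the_strongest_peak(self):
        peaks, reads = self._world()
        top = top_n_heatmap(peaks, reads, 1, 200, 10)
        assert top.peak_names == [max(peaks, key=lambda p: p.score).name]

    def test_n_too_large_errors(self):
        peaks, reads = self._world()
        with pytest.raises(ValueError):
            top_n_heatmap(peaks, reads, len(peaks) + 1, 200, 10)


class TestColocScore:
    def _flat(self, value=1.0):
        vals = np.full((4, 40), value)
        return SignalMatrix(vals, vals, [f"p{i}" for i in range(4)],
                            np.arange(4.0), flank=200, bin_size=10,
                            total_reads=1e7)

    def test_flat_matrix_scores_one(self):
        assert coloc_score(self._flat(), 100) == pytest.approx(1.0)

    def test_all_center_signal_is_flagged_nan(self):
        mat = self._flat(0.0)
        mat.values[:, 15:25] = 5.0
        with pytest.warns(RuntimeWarning):
            assert np.isnan(coloc_score(mat, 100))

    def test_center_halfwidth_must_be_inside_flank(self):
        with pytest.raises(ValueError):
            coloc_score(self._flat(), 200)


class TestPeakOverlap:
    def test_identical_sets_fully_overlap(self):
        rng = np.random.default_rng(3)
        peaks = random_peaks(rng, 40)
        res = peak_overlap(peaks, list(peaks))
        assert res.pairwise[(0, 1)] == len(peaks)

    def test_disjoint_chromosomes_do_not_overlap(self):
        a = [make_peak("chr1", 0, 100)]
        b = [make_peak("chr2", 0, 100)]
        assert peak_overlap(a, b).pairwise[(0, 1)] == 0

    @pytest.mark.parametrize("mode", ["interval", "summit_window"])
    @pytest.mark.parametrize("seed", range(5))
    def test_random_sets_match_quadratic_oracle(self, mode, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 200, span=30_000)
        b = random_peaks(rng, 200, span=30_000)
        res = peak_overlap(a, b, mode=mode, summit_window=200)
        assert res.pairwise[(0, 1)] == sum(
            oracle_overlap_mask(a, b, mode, 200))
        assert res.pairwise[(1, 0)] == sum(
            oracle_overlap_mask(b, a, mode, 200))


class TestConservation:
    def test_identical_sets_are_fully_conserved(self):
        rng = np.random.default_rng(4)
        peaks = random_peaks(rng, 100)
        res = conservation([peaks, list(peaks), list(peaks)])
        assert res.kway == 100
        assert res.conserved_fractions == [1.0, 1.0, 1.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_kway_bounded_by_pairwise(self, seed):
        rng = np.random.default_rng(seed)
        sets = [random_peaks(rng, 80, span=20_000) for _ in range(3)]
        res = conservation(sets)
        pair_min = min(res.pairwise[(0, j)] for j in (1, 2))
        assert res.kway <= pair_min
        for (i, j), v in res.pairwise.items():
            assert v <= min(len(sets[i]), len(sets[j]))

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            conservation([random_peaks(np.random.default_rng(0), 5)])


class TestNearestDistances:
    def test_sign_convention(self):
        a = [make_peak("chr1", 800, 1000, 900)]
        b = [make_peak("chr1", 1000, 1100, 1050)]
        records, _ = nearest_peak_distances(a, b)
        assert records[0].distance == -150

    def test_self_distances_are_zero(self):
        rng = np.random.default_rng(5)
        peaks = random_peaks(rng, 30)
        records, summary = nearest_peak_distances(peaks, list(peaks))
        assert all(r.distance == 0 for r in records)
        assert summary["median_abs_distance"] == 0

    def test_tie_breaks_toward_upstream(self):
        a = [make_peak("chr1", 950, 1050, 1000)]
        b = [make_peak("chr1", 850, 950, 900),
             make_peak("chr1", 1050, 1150, 1100)]
        records, _ = nearest_peak_distances(a, b)
        assert records[0].distance == -100

    def test_gene_orientation_flips_minus_strand(self):
        a = [make_peak("chr1", 800, 1000, 900)]
        b = [make_peak("chr1", 1000, 1100, 1050)]
        records, _ = nearest_peak_distances(a, b, orientation="gene",
                                            strands_a=["-"])
        assert records[0].distance == 150

    def test_chromosome_without_b_peaks_is_dropped_and_counted(self):
        a = [make_peak("chr1", 0, 100), make_peak("chrX", 0, 100)]
        b = [make_peak("chr1", 50, 150, 100)]
        records, summary = nearest_peak_distances(a, b)
        assert len(records) == 1
        assert summary["dropped_no_b_on_chrom"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_peaks(rng, 300, span=40_000)
        b = random_peaks(rng, 300, span=40_000)
        records, _ = nearest_peak_distances(a, b)
        expect = [d for d in oracle_nearest(a, b) if d is not None]
        assert [r.distance for r in records] == expect


class TestPlantedColocalization:
    def test_planted_share_recovered_and_null_pair_uncorrelated(
            self, small_world):
        """Two cell lines planted to share 90% of line1's sites recover
        ~0.9 pairwise conservation; factors with no planted pair stay
        near-independent."""
        w = small_world
        tf = w.truth.factor_peaks["tf"]
        pol = w.truth.factor_peaks["pol"]
        res = peak_overlap(tf, pol, mode="summit_window", summit_window=300)
        frac = res.pairwise[(0, 1)] / len(tf)
        band = 3 * np.sqrt(0.9 * 0.1 / len(tf))
        assert abs(frac - 0.9) <= band + 0.05
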