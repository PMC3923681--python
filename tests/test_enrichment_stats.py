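import numpy as np
import pytest
from scipy import stats

from cohesichip.enrichment_stats import (MotifSpec, assign_genes_to_peaks,
                                         fisher_2x2, gene_list_overlap_test,
                                         motif_enrichment_vs_random_promoters,
                                         motif_site_fraction, scan_motif)
from cohesichip.synthetic_data import simulate_promoter_sequences
from conftest import make_gene, make_peak, random_genes, random_peaks
from oracles import (oracle_assign_genes, oracle_fisher_two_sided,
                     oracle_overlap_p_by_enumeration, oracle_scan)

CCAAT = MotifSpec(name="ccaat", consensus="CCAAT")


class TestScanMotif:
    def test_forward_hit(self):
        assert scan_motif("TTCCAATT", CCAAT) == [(2, "+")]

    def test_reverse_complement_hit(self):
        assert scan_motif("TTATTGGTT", CCAAT) == [(2, "-")]

    def test_n_never_matches(self):
        assert scan_motif("CCNAT", CCAAT) == []

    def test_iupac_degenerate_codes(self):
        m = MotifSpec(name="gcbox", consensus="GGGCGG")
        assert scan_motif("AGGGCGGA", m) == [(1, "+")]
        m2 = MotifSpec(name="ry", consensus="RRYY")
        assert (0, "+") in scan_motif("AGCT", m2)

    def test_invalid_residue_errors(self):
        with pytest.raises(ValueError):
            scan_motif("ACGU", CCAAT)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequence_matches_sliding_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10_000))
        for consensus in ("CCAAT", "CANNTG", "RRCCAATYY"):
            m = MotifSpec(name=consensus, consensus=consensus)
            assert scan_motif(seq, m) == oracle_scan(seq, consensus)

    def test_pwm_at_full_threshold_equals_consensus(self):
        rows = {"A": (1.0, 0, 0, 0), "C": (0, 1.0, 0, 0),
                "G": (0, 0, 1.0, 0), "T": (0, 0, 0, 1.0)}
        pwm = MotifSpec(name="pwm", pwm=tuple(rows[c] for c in "CCAAT"),
                        threshold=1.0)
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2_000))
        assert scan_motif(seq, pwm) == scan_motif(seq, CCAAT)


class TestMotifSiteFraction:
    def test_every_sequence_is_the_consensus(self):
        frac, _, _ = motif_site_fraction(["CCAAT"] * 10, CCAAT)
        assert frac == 1.0

    def test_motif_absent(self):
        frac, _, _ = motif_site_fraction(["AAAAAAA"] * 10, CCAAT)
        assert frac == 0.0

    def test_planted_occupancy_recovered(self):
        rng = np.random.default_rng(2)
        seqs, planted = simulate_promoter_sequences(1_000, 0.8, "CCAAT",
                                                    101, rng)
        frac, (lo, hi), k = motif_site_fraction(seqs, CCAAT)
        assert k == planted.sum()  # background is motif-free by rejection
        assert abs(frac - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / 1_000)


class TestFisher:
    def test_worked_odds_ratio(self):
        odds, p = fisher_2x2(80, 20, 40, 60)
        assert odds == pytest.approx(6.0)
        assert p == pytest.approx(oracle_fisher_two_sided(80, 20, 40, 60))

    def test_null_table(self):
        odds, p = fisher_2x2(30, 70, 30, 70)
        assert odds == pytest.approx(1.0)
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
        if a + b == 0 or c + d == 0:
            a, d = a + 1, d + 1
        _, p = fisher_2x2(a, b, c, d)
        assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d),
                                  rel=1e-9)


class TestMotifEnrichment:
    def _promoters(self, seed, occ_bound=0.8, occ_bg=0.4, n=120, pool=400):
        rng = np.random.default_rng(seed)
        bound_seqs, _ = simulate_promoter_sequences(n, occ_bound, "CCAAT",
                                                    101, rng)
        all_seqs, _ = simulate_promoter_sequences(pool, occ_bg, "CCAAT",
                                                  101, rng)
        bound = {f"b{i}": s for i, s in enumerate(bound_seqs)}
        universe = dict(bound)
        universe.update({f"u{i}": s for i, s in enumerate(all_seqs)})
        return bound, universe

    def test_detects_planted_preference(self):
        bound, universe = self._promoters(0)
        res = motif_enrichment_vs_random_promoters(bound, universe, CCAAT,
                                                   seed=5)
        assert res.p_value < 1e-4 and res.odds_ratio > 1

    def test_draw_excludes_bound_and_is_seeded(self):
        bound, universe = self._promoters(1)
        r1 = motif_enrichment_vs_random_promoters(bound, universe, CCAAT, 7)
        r2 = motif_enrichment_vs_random_promoters(bound, universe, CCAAT, 7)
        assert (r1.a, r1.b, r1.c, r1.d, r1.p_value) == \
               (r2.a, r2.b, r2.c, r2.d, r2.p_value)

    def test_redraw_distribution_reported(self):
        bound, universe = self._promoters(2)
        res = motif_enrichment_vs_random_promoters(bound, universe, CCAAT, 3,
                                                   n_redraws=5)
        assert len(res.p_values_redraws) == 5

    def test_empty_bound_set_errors(self):
        with pytest.raises(ValueError):
            motif_enrichment_vs_random_promoters({}, {"u": "ACGTACGT"},
                                                 CCAAT, 0)

    def test_insufficient_pool_errors(self):
        with pytest.raises(ValueError):
            motif_enrichment_vs_random_promoters(
                {"b1": "ACGTACGT", "b2": "ACGTACGT"}, {"b1": "ACGTACGT"},
                CCAAT, 0)


class TestGeneListOverlap:
    def test_small_universe_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        reference = universe[:4]
        query = universe[2:7]  # overlap 2 with reference
        res = gene_list_overlap_test(query, reference, universe,
                                     n_resamples=0)
        dist = oracle_overlap_p_by_enumeration(universe, len(query),
                                               reference)
        p_obs = dist[res.extra["observed_overlap"]]
        expect = sum(p for k, p in dist.items()
                     if p <= p_obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(expect, rel=1e-9)

    def test_overlap_at_expectation_gives_unit_fold(self):
        universe = [f"g{i}" for i in range(20)]
        query = universe[:5]
        reference = universe[:1] + universe[5:8]  # overlap 1 = 5*4/20
        res = gene_list_overlap_test(query, reference, universe,
                                     n_resamples=0)
        assert res.extra["fold"] == pytest.approx(1.0)

    def test_same_seed_reproduces_empirical_p(self):
        universe = [f"g{i}" for i in range(50)]
        res1 = gene_list_overlap_test(universe[:8], universe[4:14], universe,
                                      seed=3, n_resamples=500)
        res2 = gene_list_overlap_test(universe[:8], universe[4:14], universe,
                                      seed=3, n_resamples=500)
        assert res1.empirical_p == res2.empirical_p

    def test_gene_outside_universe_errors(self):
        with pytest.raises(ValueError, match="gX"):
            gene_list_overlap_test(["gX"], ["g1"], ["g1", "g2"])

    def test_empirical_p_converges_to_exact_tail(self):
        universe = [f"g{i}" for i in range(20)]
        reference = universe[:4]
        query = universe[2:7]
        res = gene_list_overlap_test(query, reference, universe, seed=0,
                                     n_resamples=20_000)
        obs = res.extra["observed_overlap"]
        exact_tail = float(stats.hypergeom.sf(obs - 1, 20, 4, 5))
        mc_sd = np.sqrt(exact_tail * (1 - exact_tail) / 20_000)
        assert abs(res.empirical_p - exact_tail) <= 2 * mc_sd + 1e-4


class TestAssignGenes:
    def test_peak_one_bp_outside_window_excluded(self):
        g = make_gene("g", "chr1", "+", 10_000, 12_000)
        inside = [make_peak("chr1", 12_000 + 1_999, 12_000 + 2_300)]
        outside = [make_peak("chr1", 12_000 + 2_000, 12_000 + 2_300)]
        assert assign_genes_to_peaks(inside, [g], 2_000) == ["g"]
        assert assign_genes_to_peaks(outside, [g], 2_000) == []

    def test_zero_window_includes_gene_body_peak(self):
        g = make_gene("g", "chr1", "+", 10_000, 12_000)
        pk = [make_peak("chr1", 10_500, 10_800)]
        assert assign_genes_to_peaks(pk, [g], 0) == ["g"]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = random_genes(rng, 40)
        peaks = random_peaks(rng, 100)
        assert assign_genes_to_peaks(peaks, genes, 2_000) == \
            oracle_assign_genes(peaks, genes, 2_000)
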