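"""EM haplotype frequencies, LD statistics, greedy tagging and two-tag rescue."""

import itertools

import numpy as np
import pandas as pd
import pytest

from asekit import ld_tagging as ld
from asekit import synthetic_cohort as sc
from conftest import hwe_genotypes


def genotype_loglik(counts_by_geno, p11, pA, pB):
    """Independent oracle: two-locus genotype log-likelihood as a function of
    p11 with the allele margins held at their observed values."""
    p10, p01 = pA - p11, pB - p11
    p00 = 1.0 - pA - pB + p11
    prob = {
        (0, 0): p00 ** 2, (0, 1): 2 * p00 * p01, (0, 2): p01 ** 2,
        (1, 0): 2 * p00 * p10, (1, 1): 2 * p10 * p01 + 2 * p11 * p00,
        (1, 2): 2 * p01 * p11, (2, 0): p10 ** 2, (2, 1): 2 * p10 * p11,
        (2, 2): p11 ** 2,
    }
    ll = 0.0
    for g, cnt in counts_by_geno.items():
        ll += cnt * np.log(max(prob[g], 1e-300))
    return ll


class TestEM:
    def test_no_double_hets_equals_direct_counting(self):
        ga = np.array([0, 2, 1, 0, 2, 1])
        gb = np.array([0, 2, 0, 1, 2, 2])  # no subject is het at both
        pair = ld.em_haplotype_freqs(ga, gb)
        # direct gamete counting: with no double heterozygote every subject's
        # two haplotypes are determined
        expected = {(1, 1): 5, (1, 0): 1, (0, 1): 2, (0, 0): 4}
        total = 12
        assert pair.hap_freqs[0] == pytest.approx(expected[(1, 1)] / total, abs=1e-9)
        assert pair.hap_freqs[1] == pytest.approx(expected[(1, 0)] / total, abs=1e-9)
        assert pair.hap_freqs[2] == pytest.approx(expected[(0, 1)] / total, abs=1e-9)

    def test_identical_columns_perfect_correlation(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1, 1])
        pair = ld.ld_stats(ld.em_haplotype_freqs(g, g))
        p11, p10, p01, _ = pair.hap_freqs
        assert p11 == pytest.approx(pair.allele_freqs[0], abs=1e-8)
        assert p10 == pytest.approx(0.0, abs=1e-8)
        assert p01 == pytest.approx(0.0, abs=1e-8)
        assert pair.r2 == pytest.approx(1.0, abs=1e-8)

    def test_insufficient_data(self):
        with pytest.raises(ld.InsufficientDataError):
            ld.em_haplotype_freqs([1], [1])

    def test_em_matches_grid_search_on_small_datasets(self):
        """EM log-likelihood within 1e-6 of a dense 1-D grid over p11 (the
        allele margins are fixed by the genotype counts) - 20 random
        datasets of at most 12 subjects."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 20:
            p = np.sort(rng.dirichlet(np.ones(4)))[::-1]
            n = int(rng.integers(4, 13))
            ga, gb = hwe_genotypes(rng, *p, n)
            if len(set(ga)) == 1 or len(set(gb)) == 1:
                continue  # monomorphic draw: likelihood flat in p11
            pair = ld.em_haplotype_freqs(ga, gb)
            pA, pB = pair.allele_freqs
            counts = {}
            for g in zip(ga, gb):
                counts[g] = counts.get(g, 0) + 1
            lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
            grid = np.linspace(lo, hi, max(2, int((hi - lo) / 1e-5)))
            best = max(genotype_loglik(counts, x, pA, pB) for x in grid)
            assert pair.loglik >= best - 1e-6
            checked += 1

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            p = rng.dirichlet(np.ones(4))
            ga, gb = hwe_genotypes(rng, *p, 40)
            pair = ld.em_haplotype_freqs(ga, gb)
            trace = np.array(pair.loglik_trace)
            assert (np.diff(trace) >= -1e-10).all()
            assert pair.converged

    def test_symmetry_and_allele_relabeling(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            p = rng.dirichlet(np.ones(4))
            ga, gb = hwe_genotypes(rng, *p, 30)
            if len(set(ga)) == 1 or len(set(gb)) == 1:
                continue
            r_ab = ld.r2_between(ga, gb)
            r_ba = ld.r2_between(gb, ga)
            r_flip = ld.r2_between(2 - ga, gb)
            assert r_ab == pytest.approx(r_ba, abs=1e-12)
            assert r_ab == pytest.approx(r_flip, abs=1e-10)

    def test_phased_draws_with_two_haplotypes_match_direct_counts(self):
        """When only coupling haplotypes exist, the EM solution equals the
        directly counted haplotype frequencies of the phased draw."""
        panel = sc.HaplotypePanel(("a", "b"), [[0, 0], [1, 1]], [0.7, 0.3])
        subjects = sc.draw_subjects(panel, 60, seed=8)
        ga = np.array([s.haplotype_a[0] + s.haplotype_b[0] for s in subjects])
        gb = np.array([s.haplotype_a[1] + s.haplotype_b[1] for s in subjects])
        direct_p11 = np.mean([h[0] == 1 for s in subjects
                              for h in (s.haplotype_a, s.haplotype_b)])
        pair = ld.em_haplotype_freqs(ga, gb)
        assert pair.hap_freqs[0] == pytest.approx(direct_p11, abs=1e-8)
        assert pair.hap_freqs[1] == pytest.approx(0.0, abs=1e-8)


class TestLDStats:
    def test_hand_computed_case(self):
        pair = ld.PairLD("a", "b", (0.35, 0.15, 0.15, 0.35), (0.5, 0.5))
        ld.ld_stats(pair)
        assert pair.D == pytest.approx(0.10)
        assert pair.r2 == pytest.approx(0.16)
        assert pair.D_prime == pytest.approx(0.4)

    def test_equilibrium_and_coupling(self):
        eq = ld.ld_stats(ld.PairLD("a", "b", (0.12, 0.18, 0.28, 0.42), (0.3, 0.4)))
        assert eq.D == pytest.approx(0.0, abs=1e-12)
        assert eq.r2 == pytest.approx(0.0, abs=1e-12)
        cpl = ld.ld_stats(ld.PairLD("a", "b", (0.3, 0.0, 0.0, 0.7), (0.3, 0.3)))
        assert cpl.D_prime == pytest.approx(1.0)
        assert cpl.r2 == pytest.approx(1.0)

    def test_monomorphic_r2_undefined_not_zero(self):
        pair = ld.ld_stats(ld.PairLD("a", "b", (0.0, 0.0, 0.4, 0.6), (0.0, 0.4)))
        assert pair.r2 is None


def draw_genotypes(blocks, n, seed):
    cfg = sc.SimulationConfig(
        marker_snp_ids=(blocks[0].snp_ids[0],),
        causal_snp_id=blocks[0].snp_ids[0], panel_blocks=blocks)
    panel = sc.build_panel(cfg)
    return sc.genotype_matrix(sc.draw_subjects(panel, n, seed)), panel


class TestGreedyTag:
    def test_single_cluster_single_tag(self):
        blocks = (sc.PanelBlock(("a", "b", "c", "d"),
                                ((0, 0, 0, 0), (1, 1, 1, 1)), (0.7, 0.3)),)
        geno, _ = draw_genotypes(blocks, 200, 1)
        ts = ld.greedy_tag(geno)
        assert len(ts.tags) == 1
        assert ts.n_covered_at_threshold == ts.n_common == 4
        assert ts.mean_r2 == pytest.approx(1.0)

    def test_independent_snps_all_self_tag(self):
        blocks = tuple(sc.PanelBlock((s,), ((0,), (1,)), (0.6, 0.4))
                       for s in "abcde")
        geno, _ = draw_genotypes(blocks, 400, 2)
        ts = ld.greedy_tag(geno)
        assert sorted(ts.tags) == list("abcde")
        assert all(e["kind"] == "self" for e in ts.proxy_map.values())

    def test_planted_three_clusters_recovered(self):
        blocks = (
            sc.PanelBlock(("a1", "a2", "a3"), ((0, 0, 0), (1, 1, 1)), (0.6, 0.4)),
            sc.PanelBlock(("b1", "b2", "b3"), ((0, 0, 0), (1, 1, 1)), (0.75, 0.25)),
            sc.PanelBlock(("c1", "c2"), ((0, 0), (1, 1)), (0.5, 0.5)),
        )
        geno, _ = draw_genotypes(blocks, 300, 3)
        ts = ld.greedy_tag(geno)
        assert len(ts.tags) == 3
        assert ts.n_covered_at_threshold == ts.n_common == 8
        for snp, entry in ts.proxy_map.items():
            proxy = entry["proxy"] if entry["kind"] != "haplotype" else None
            assert proxy is not None and proxy[0] == snp[0]  # same cluster prefix

    def test_all_rare_snps_empty_tagset_with_warning(self):
        blocks = tuple(sc.PanelBlock((s,), ((0,), (1,)), (0.99, 0.01))
                       for s in "ab")
        geno, _ = draw_genotypes(blocks, 500, 4)
        ts = ld.greedy_tag(geno, maf_threshold=0.05)
        assert ts.tags == [] and ts.n_common == 0
        assert any("MAF" in w for w in ts.warnings)

    def test_exhaustive_matches_greedy_on_clusters(self):
        blocks = (
            sc.PanelBlock(("a1", "a2"), ((0, 0), (1, 1)), (0.6, 0.4)),
            sc.PanelBlock(("b1", "b2"), ((0, 0), (1, 1)), (0.7, 0.3)),
        )
        geno, _ = draw_genotypes(blocks, 300, 5)
        greedy = ld.greedy_tag(geno)
        exact = ld.greedy_tag(geno, exhaustive=True)
        assert len(exact.tags) == len(greedy.tags) == 2

    def test_reported_proxy_r2_recomputable(self):
        blocks = (
            sc.PanelBlock(("a1", "a2", "a3"), ((0, 0, 0), (1, 1, 0), (1, 1, 1)),
                          (0.5, 0.2, 0.3)),
            sc.PanelBlock(("b1", "b2"), ((0, 0), (1, 1)), (0.7, 0.3)),
        )
        geno, _ = draw_genotypes(blocks, 250, 6)
        ts = ld.greedy_tag(geno)
        for snp, entry in ts.proxy_map.items():
            if entry["kind"] == "single":
                again = ld.r2_between(geno[entry["proxy"]], geno[snp])
                assert again == pytest.approx(entry["r2"], abs=1e-10)


AND_HAPLOTYPES = pd.DataFrame(
    [[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 0]],
    columns=["t1", "t2", "target"])


class TestTwoTagHaplotype:
    def test_self_proxy_is_perfect(self):
        geno = pd.DataFrame({"t1": [0, 1, 2, 1, 0, 2], "t2": [0, 0, 1, 2, 1, 2]})
        res = ld.two_tag_haplotype_r2("t1", ("t1", "t2"), geno)
        assert res["r2"] == pytest.approx(1.0, abs=1e-8)

    def test_independent_target_near_zero(self):
        rng = np.random.default_rng(10)
        geno = pd.DataFrame({
            "t1": rng.binomial(2, 0.5, 500), "t2": rng.binomial(2, 0.5, 500),
            "target": rng.binomial(2, 0.3, 500)})
        res = ld.two_tag_haplotype_r2("target", ("t1", "t2"), geno)
        assert res["r2"] < 0.05

    def test_and_target_rescued_only_by_haplotype(self):
        """Target = AND of two independent half-frequency tags: each single
        tag gives r2 = 1/3 but the (1,1) two-tag haplotype gives r2 = 1."""
        res = ld.two_tag_haplotype_r2(
            "target", ("t1", "t2"), haplotypes=AND_HAPLOTYPES)
        assert res["r2"] == pytest.approx(1.0)
        assert res["haplotype"] == (1, 1)
        # direct-count verification of the single-tag r2 from the same panel
        hap = AND_HAPLOTYPES.to_numpy()
        p_t1, p_tar = 0.5, 0.25
        p11 = np.mean((hap[:, 0] == 1) & (hap[:, 2] == 1))
        d = p11 - p_t1 * p_tar
        single = d * d / (p_t1 * 0.5 * p_tar * 0.75)
        assert single == pytest.approx(1 / 3)
        assert single < 0.8

    def test_em_path_agrees_with_phased_counting(self):
        blocks = (sc.PanelBlock(("t1", "t2", "target"),
                                tuple(map(tuple, AND_HAPLOTYPES.to_numpy())),
                                (0.25, 0.25, 0.25, 0.25)),)
        geno, _ = draw_genotypes(blocks, 500, 11)
        res = ld.two_tag_haplotype_r2("target", ("t1", "t2"), geno)
        assert res["haplotype"] == (1, 1)
        assert res["r2"] > 0.8


class TestCoverage:
    def test_saturated_tagging(self):
        blocks = tuple(sc.PanelBlock((s,), ((0,), (1,)), (0.6, 0.4))
                       for s in "abc")
        geno, _ = draw_genotypes(blocks, 300, 12)
        rep = ld.coverage_report(ld.greedy_tag(geno))
        assert rep["mean_r2"] == pytest.approx(1.0)
        assert rep["n_covered_at_threshold"] == rep["n_common"] == 3

    def test_single_snp_panel(self):
        blocks = (sc.PanelBlock(("only",), ((0,), (1,)), (0.5, 0.5)),)
        geno, _ = draw_genotypes(blocks, 100, 13)
        rep = ld.coverage_report(ld.greedy_tag(geno))
        assert rep["mean_r2"] == pytest.approx(1.0) and rep["n_common"] == 1

    def test_two_tag_rescue_completes_coverage(self):
        """One SNP coverable only by a haplotype of two tags: after rescue the
        report shows full coverage with no extra tag promoted."""
        blocks = (sc.PanelBlock(
            ("t1", "f1", "t2", "f2", "andsnp"),
            ((1, 1, 1, 1, 1), (1, 1, 0, 0, 0), (0, 0, 1, 1, 0), (0, 0, 0, 0, 0)),
            (0.25, 0.25, 0.25, 0.25)),)
        geno, _ = draw_genotypes(blocks, 600, 14)
        ts = ld.greedy_tag(geno)
        rep = ld.coverage_report(ts)
        assert len(ts.tags) == 2
        assert ts.proxy_map["andsnp"]["kind"] == "haplotype"
        assert rep["n_covered_at_threshold"] == rep["n_common"] == 5
        assert rep["mean_r2"] >= 0.8
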