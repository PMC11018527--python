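import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polykit import popstats
from polykit.popstats import FilterRules
from polykit.synthdata import SimConfig, gen_genotypes

from conftest import make_matrix
from oracles import bh_adjust, pi_pairwise, tajima_d_direct, wc_theta_site


class TestWindowedPi:
    def test_monomorphic_window_zero(self):
        g = make_matrix(np.zeros((4, 10)), contig_lengths={"chr1": 1000})
        df, mean = popstats.windowed_pi(g, window_bp=1000, step_bp=1000)
        assert mean == 0.0

    def test_single_site_hand_value(self):
        g = make_matrix([[1], [1]], contig_lengths={"chr1": 1000})
        df, mean = popstats.windowed_pi(g, window_bp=1000, step_bp=1000)
        # p = 0.5 among 4 haplotypes: 2 * 0.25 * (4/3) / 1000
        assert mean == pytest.approx(2 * 0.25 * (4 / 3) / 1000)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(8, 40))
        g = make_matrix(geno, contig_lengths={"chr1": 40})
        df, mean = popstats.windowed_pi(g, window_bp=40, step_bp=40)
        expected = pi_pairwise(geno).sum() / 40
        assert mean == pytest.approx(expected, abs=1e-12)

    def test_bad_window_rejected(self):
        g = make_matrix([[1], [1]])
        with pytest.raises(ValueError):
            popstats.windowed_pi(g, window_bp=0)

    def test_sliding_step(self):
        g = make_matrix(np.ones((4, 5), dtype=int), pos=[10, 20, 30, 40, 50],
                        contig_lengths={"chr1": 300})
        df, _ = popstats.windowed_pi(g, window_bp=100, step_bp=50)
        assert len(df) == 5  # starts 1, 51, 101, 151, 201


class TestTajimaD:
    def test_zero_numerator(self):
        c = popstats.tajima_constants(6)
        s = 5
        assert popstats.tajima_d(s / c["a1"], s, 6) == pytest.approx(0.0)

    def test_hand_value_n4(self):
        d = popstats.tajima_d(1.5, 3, 4)
        assert d == pytest.approx(tajima_d_direct(1.5, 3, 4), abs=1e-12)
        assert d == pytest.approx(-0.755, abs=2e-3)

    def test_constants_n4(self):
        c = popstats.tajima_constants(4)
        assert c["a1"] == pytest.approx(11 / 6)

    def test_too_few_haplotypes(self):
        with pytest.raises(ValueError):
            popstats.tajima_constants(3)

    def test_windowed_matches_oracle(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(6, 30))
        g = make_matrix(geno, contig_lengths={"chr1": 500})
        df, mean = popstats.windowed_tajima_d(g, window_bp=500)
        pi_sum = pi_pairwise(geno).sum()
        ac = geno.sum(axis=0)
        s = int(((ac > 0) & (ac < 12)).sum())
        assert mean == pytest.approx(tajima_d_direct(pi_sum, s, 12), abs=1e-10)

    def test_empty_window_nan_excluded(self):
        g = make_matrix(np.zeros((4, 3)), contig_lengths={"chr1": 2000})
        df, mean = popstats.windowed_tajima_d(g, window_bp=1000)
        assert df["value"].isna().all()
        assert np.isnan(mean)


class TestFst:
    def test_fixed_difference(self):
        g = make_matrix([[2], [2], [0], [0]])
        theta = popstats.wc_fst_sites(g, ["s0", "s1"], ["s2", "s3"])
        assert theta[0] == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        # all heterozygotes in both populations: a = 0 exactly
        g = make_matrix(np.ones((8, 1), dtype=int))
        theta = popstats.wc_fst_sites(g, [f"s{i}" for i in range(4)],
                                      [f"s{i}" for i in range(4, 8)])
        assert abs(theta[0]) < 1e-12

    def test_hand_value_hwe(self):
        # p = 0.2 / 0.8 with exact HWE counts needs 25 diploids per pop:
        # 16 hom-ref + 8 het + 1 hom-alt (h = 0.32); theta = 0.5196 by hand
        pop_a = [0] * 16 + [1] * 8 + [2]
        pop_b = [2] * 16 + [1] * 8 + [0]
        g = make_matrix(np.array([pop_a + pop_b]).T.reshape(50, 1))
        theta = popstats.wc_fst_sites(g, [f"s{i}" for i in range(25)],
                                      [f"s{i}" for i in range(25, 50)])
        a = 0.18 - (0.25 - 0.09 - 0.08) / 24
        b = (25 / 24) * (0.25 - 0.09 - (49 / 100) * 0.32)
        assert theta[0] == pytest.approx(a / (a + b + 0.16), abs=1e-12)
        assert theta[0] == pytest.approx(wc_theta_site(pop_a, pop_b), abs=1e-12)

    def test_sites_match_oracle_random(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, size=(12, 1000))
        g = make_matrix(geno)
        a_samples = [f"s{i}" for i in range(6)]
        b_samples = [f"s{i}" for i in range(6, 12)]
        theta = popstats.wc_fst_sites(g, a_samples, b_samples)
        for j in range(0, 1000, 13):
            expected = wc_theta_site(geno[:6, j], geno[6:, j])
            if np.isnan(expected):
                assert np.isnan(theta[j])
            else:
                assert theta[j] == pytest.approx(expected, abs=1e-12)

    def test_gene_fst_flanks(self):
        geno = np.array([[2, 0], [2, 0], [0, 0], [0, 0]])
        g = make_matrix(geno, pos=[100, 5000])
        genes = pd.DataFrame(
            {"gene_id": ["g1"], "chrom": ["chr1"], "start": [50], "end": [150]}
        )
        out = popstats.gene_fst(g, ["s0", "s1"], ["s2", "s3"], genes, flank_bp=2000)
        assert out["n_sites"].iloc[0] == 1  # second site outside gene +/- flank
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_gene_without_sites_nan(self):
        g = make_matrix([[1], [0], [1], [0]], pos=[10_000])
        genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"], "start": [1], "end": [100]})
        out = popstats.gene_fst(g, ["s0", "s1"], ["s2", "s3"], genes)
        assert np.isnan(out["fst"].iloc[0])


class TestSnpFilter:
    def test_max_missing(self):
        geno = np.zeros((10, 2), dtype=int)
        geno[:5, 0] = -1  # 50% missing > 40%
        geno[1, 1] = 1
        g = make_matrix(geno)
        out, log = popstats.snp_filter(g, FilterRules(max_missing=0.4))
        assert out.n_sites == 1
        assert log["max_missing"] == 1

    def test_min_maf(self):
        geno = np.zeros((10, 2), dtype=int)
        geno[0, 0] = 1  # MAF 0.05
        geno[:4, 1] = 1  # MAF 0.2
        g = make_matrix(geno)
        out, log = popstats.snp_filter(g, FilterRules(min_maf=0.10))
        assert out.n_sites == 1
        assert log["min_maf"] == 1

    def test_ld_prune_keeps_earlier(self):
        rng = np.random.default_rng(3)
        col = rng.integers(0, 3, size=10)
        geno = np.column_stack([col, col, rng.integers(0, 3, size=10)])
        g = make_matrix(geno)
        out, log = popstats.snp_filter(g, FilterRules(ld_r2=0.4))
        assert log["ld_prune"] == 1
        assert out.pos[0] == 1  # earlier site kept

    def test_het_in_control(self):
        geno = np.zeros((3, 3), dtype=int)
        geno[0] = [1, 0, 2]  # control het at site 0
        g = make_matrix(geno)
        out, log = popstats.snp_filter(g, FilterRules(het_in_control="s0"))
        assert out.n_sites == 2
        assert log["het_in_control"] == 1

    def test_missing_control_rejected(self):
        g = make_matrix([[0], [0]])
        with pytest.raises(ValueError):
            popstats.snp_filter(g, FilterRules(het_in_control="nope"))

    def test_repeat_mask(self):
        g = make_matrix(np.zeros((2, 3), dtype=int), pos=[5, 15, 25])
        mask = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]})
        out, log = popstats.snp_filter(g, FilterRules(repeat_mask=mask))
        assert list(out.pos) == [5, 25]


class TestPolarize:
    def test_majority_vote(self):
        # outgroup haplotypes A,A,A,G -> one het + one hom-ref diploid
        g = make_matrix([[0], [1], [0], [0]])
        anc = popstats.polarize_ancestral(g, ["s0", "s1"])
        assert anc[0] == 0

    def test_tie_unresolved(self):
        g = make_matrix([[1], [1]])
        anc = popstats.polarize_ancestral(g, ["s0", "s1"])
        assert anc[0] == -1

    def test_all_missing_unresolved(self):
        g = make_matrix([[-1], [0]])
        anc = popstats.polarize_ancestral(g, ["s0"])
        assert anc[0] == -1


class TestSfs:
    def test_counting_example(self):
        geno = np.zeros((5, 4), dtype=int)
        geno[0, 0] = 1
        geno[1, 1] = 1
        geno[2, 2] = 1
        geno[0, 3] = 2  # derived count 2
        anc = np.zeros(4, dtype=np.int8)
        g = make_matrix(geno, ancestral=anc)
        res = popstats.sfs(g, polarized=True)
        assert res.spectrum.tolist() == [3, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_folded_equals_fold_of_unfolded(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(6, 200))
        anc = np.zeros(200, dtype=np.int8)  # all resolved -> same site sets
        g = make_matrix(geno, ancestral=anc)
        unfolded = popstats.sfs(g, polarized=True)
        folded = popstats.sfs(g, polarized=False)
        assert np.array_equal(popstats.fold_sfs(unfolded.spectrum), folded.spectrum)

    def test_conservation(self):
        cfg = SimConfig(seed=30, n_sites=2000, missing_rate=0.05)
        g, pm, _ = gen_genotypes(cfg)
        samples = pm.samples_with("wild")
        res = popstats.sfs(g, samples, polarized=True)
        sub = g._sub(samples)
        complete = (sub >= 0).all(axis=0)
        ac = sub[:, complete].sum(axis=0)
        segregating = int(((ac > 0) & (ac < 2 * len(samples))).sum())
        resolved = g.ancestral[complete] >= 0
        seg_mask = (ac > 0) & (ac < 2 * len(samples))
        assert res.n_used + int((seg_mask & ~resolved).sum()) == segregating

    def test_neutral_spectrum_goodness_of_fit(self):
        cfg = SimConfig(seed=31, pop_split_fst=0.0, n_sites=10_000)
        g, pm, _ = gen_genotypes(cfg)
        res = popstats.sfs(g, pm.samples_with("wild", "cultivar"), polarized=True)
        k = np.arange(1, res.spectrum.size + 1)
        expected = (1.0 / k) / (1.0 / k).sum() * res.spectrum.sum()
        _, p = stats.chisquare(res.spectrum, expected)
        assert p > 0.01

    def test_unpolarized_without_ancestral_rejected(self):
        g = make_matrix([[1], [0]])
        with pytest.raises(ValueError):
            popstats.sfs(g, polarized=True)


class TestF3:
    def test_target_equals_source(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 3, size=(6, 50))
        geno = np.vstack([geno[:2], geno[:2], geno[2:4]])  # target == source_a
        g = make_matrix(geno)
        res = popstats.f3_statistic(g, ["s0", "s1"], ["s2", "s3"], ["s4", "s5"], block_bp=10)
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_forced_arithmetic(self):
        # t = 0.5, a = 0, b = 1 at every site
        geno = np.array([[1] * 20, [0] * 20, [2] * 20])
        g = make_matrix(geno)
        res = popstats.f3_statistic(g, ["s0"], ["s1"], ["s2"], block_bp=5)
        assert res.estimate == pytest.approx(-0.25)
        assert res.n_blocks == 5

    def test_single_block_flagged(self):
        geno = np.array([[1, 1], [0, 0], [2, 2]])
        g = make_matrix(geno)
        res = popstats.f3_statistic(g, ["s0"], ["s1"], ["s2"], block_bp=10**9)
        assert res.flagged
        assert np.isnan(res.se)

    def test_admixed_target_strongly_negative(self):
        cfg = SimConfig(seed=32, pop_split_fst=0.15, n_sites=5000, n_hybrid=10)
        g, pm, _ = gen_genotypes(cfg)
        res = popstats.f3_statistic(
            g, pm.samples_with("hybrid"), pm.samples_with("wild"),
            pm.samples_with("cultivar"), block_bp=20_000, het_correction=True,
        )
        assert res.z < -3

    def test_unadmixed_target_not_negative(self):
        cfg = SimConfig(seed=33, pop_split_fst=0.15, n_sites=5000, n_hybrid=10)
        g, pm, _ = gen_genotypes(cfg)
        res = popstats.f3_statistic(
            g, pm.samples_with("cultivar"), pm.samples_with("wild"),
            pm.samples_with("hybrid"), block_bp=20_000, het_correction=True,
        )
        assert res.z >= -1


class TestZFdr:
    def test_single_unchanged(self):
        out = popstats.z_fdr_adjust([-2.5])
        assert out[0] == pytest.approx(-2.5, abs=1e-9)

    def test_all_equal_unchanged(self):
        out = popstats.z_fdr_adjust([-1.7, -1.7, -1.7])
        assert np.allclose(out, -1.7)

    def test_hand_example(self):
        out = popstats.z_fdr_adjust([-3.0, -2.0])
        p = stats.norm.cdf([-3.0, -2.0])
        expected = stats.norm.ppf(bh_adjust(p))
        assert np.allclose(out, expected)
        assert out[0] == pytest.approx(-2.78, abs=0.01)
        assert out[1] == pytest.approx(-2.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            popstats.z_fdr_adjust([])

    @given(st.lists(st.floats(min_value=-8, max_value=8), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_order_preserving(self, zs):
        out = popstats.z_fdr_adjust(zs)
        zs = np.asarray(zs)
        # compare in p-space: the far normal tail loses a few ulp in
        # the cdf/ppf round trip
        p_raw = stats.norm.cdf(zs)
        p_adj = stats.norm.cdf(out)
        assert (p_adj >= p_raw - 1e-9).all()
        order_in = np.argsort(zs, kind="stable")
        assert (np.diff(out[order_in]) >= -1e-6).all()


class TestIntrogressionScan:
    def test_all_abba(self):
        # p2 == p3 fixed derived, p1 == outgroup fixed ancestral
        geno = np.array([[0] * 30, [2] * 30, [2] * 30, [0] * 30])
        g = make_matrix(geno, contig_lengths={"chr1": 30})
        df, genome = popstats.introgression_scan(
            g, ["s0"], ["s1"], ["s2"], ["s3"], window_bp=10
        )
        assert genome.estimate == pytest.approx(1.0)

    def test_symmetric_zero(self):
        geno = np.array([[2, 0] * 10, [0, 2] * 10, [2, 2] * 10, [0, 0] * 10])
        g = make_matrix(geno, contig_lengths={"chr1": 20})
        df, genome = popstats.introgression_scan(
            g, ["s0"], ["s1"], ["s2"], ["s3"], window_bp=20
        )
        assert genome.estimate == pytest.approx(0.0, abs=1e-12)

    def test_planted_donor_window_detected(self):
        cfg = SimConfig(seed=34, pop_split_fst=0.2, n_sites=8000, n_per_pop=10)
        g, pm, _ = gen_genotypes(cfg)
        p2 = pm.samples_with("cultivar")[:5]
        p3 = pm.samples_with("wild")[:5]
        # plant a donor block: copy p3 genotypes into p2 inside one window
        donor = (g.chrom == "chr1") & (g.pos <= 20_000)
        gt = g.genotypes.copy()
        for a, b in zip(g.sample_indices(p2), g.sample_indices(p3)):
            gt[a, donor] = gt[b, donor]
        g2 = make_matrix(gt, chrom=g.chrom, pos=g.pos, contig_lengths=g.contig_lengths)
        g2.samples = list(g.samples)
        df, _ = popstats.introgression_scan(
            g2, pm.samples_with("cultivar")[5:], p2, p3,
            pm.samples_with("outgroup_cc"), window_bp=20_000,
        )
        target = df[(df["chrom"] == "chr1") & (df["start"] == 1)]["value"].iloc[0]
        others = df[~((df["chrom"] == "chr1") & (df["start"] == 1))]["value"].dropna()
        assert target > others.quantile(0.99)

    def test_f_d_variant_runs(self):
        cfg = SimConfig(seed=35, pop_split_fst=0.1, n_sites=2000)
        g, pm, _ = gen_genotypes(cfg)
        w = pm.samples_with("wild")
        df, genome = popstats.introgression_scan(
            g, w[:5], w[5:], pm.samples_with("cultivar"),
            pm.samples_with("outgroup_cc"), window_bp=20_000, statistic="f_d",
        )
        assert np.isfinite(genome.estimate)


class TestTimeScale:
    def test_single_generation(self):
        assert popstats.generations_to_years(1).years == 21.0

    def test_paper_split_time(self):
        ts = popstats.generations_to_years(1450, 21)
        assert ts.years == 30_450.0
        assert ts.ka == 30.5

    def test_inverse(self):
        assert popstats.years_to_generations(30_450.0, 21) == pytest.approx(1450.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            popstats.generations_to_years(0)
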