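import numpy as np
import pytest
from scipy import stats as sps

from msatpop.diversity import (
    compare_groups,
    evanno_delta_k,
    global_fstats,
    hwe_tests,
    individual_heterozygosity,
    ld_tests,
    null_allele_estimates,
    population_diversity,
)
from msatpop.genotype_io import MISSING

from .conftest import make_matrix, random_matrix


class TestPopulationDiversity:
    def test_unbiased_he_hand_formula(self, toy_gm):
        # genotypes 1/1, 1/2, 2/2, 1/2: Ho = 2/4; He = (8/7)(1 - 0.5) = 4/7
        table = population_diversity(toy_gm).table
        assert table.loc["p1", "H_O"] == pytest.approx(0.5)
        assert table.loc["p1", "H_E"] == pytest.approx(8 / 7 * 0.5)

    def test_monomorphic(self):
        gm = make_matrix([[(5, 5)], [(5, 5)], [(5, 5)]], ["p1"] * 3)
        table = population_diversity(gm).table
        assert table.loc["p1", "N_A"] == 1
        assert table.loc["p1", "H_O"] == 0.0
        assert table.loc["p1", "H_E"] == 0.0

    def test_private_alleles(self, two_pop_gm):
        table = population_diversity(two_pop_gm).table
        # populations share no alleles: every allele is private
        assert table.loc["a", "P_A"] == table.loc["a", "N_A"]
        assert table.loc["b", "P_A"] == table.loc["b", "N_A"]

    def test_private_alleles_bounded_by_total(self, study_like):
        gm, _ = study_like
        table = population_diversity(gm).table.drop("Mean")
        total_distinct = sum(
            len(np.unique(gm.calls[:, l][gm.calls[:, l] != MISSING]))
            for l in range(gm.n_loci)
        )
        assert table["P_A"].sum() <= total_distinct
        assert ((0 <= table["H_O"]) & (table["H_O"] <= 1)).all()
        assert ((0 <= table["H_E"]) & (table["H_E"] <= 1)).all()

    def test_means_row_is_column_mean(self, two_pop_gm):
        table = population_diversity(two_pop_gm).table
        assert table.loc["Mean", "H_E"] == pytest.approx(
            table.drop("Mean")["H_E"].mean()
        )

    def test_fully_missing_population_errors(self):
        calls = [[(1, 2)], [(MISSING, MISSING)]]
        gm = make_matrix(calls, ["a", "b"])
        with pytest.raises(ValueError, match="no typed genotypes"):
            population_diversity(gm)


def _fstats_oracle(gm, corrected=True):
    """Direct-count implementation of Nei/Nei-Chesser basic statistics."""
    pops = gm.populations()
    idx = gm.population_index()
    ho_l, hs_l, ht_l = [], [], []
    for l in range(gm.n_loci):
        per_pop = []
        for p in pops:
            geno = [tuple(g) for g in gm.calls[idx[p], l, :] if g[0] != MISSING]
            if geno:
                per_pop.append(geno)
        if len(per_pop) < 2:
            continue
        s = len(per_pop)
        ns = [len(g) for g in per_pop]
        nh = s / sum(1 / n for n in ns)
        ho = sum(sum(a != b for a, b in g) / len(g) for g in per_pop) / s
        alleles = sorted({a for g in per_pop for pair in g for a in pair})
        fr = []
        for g in per_pop:
            flat = [a for pair in g for a in pair]
            fr.append([flat.count(a) / len(flat) for a in alleles])
        msp2 = sum(sum(f**2 for f in row) for row in fr) / s
        xbar = [sum(row[i] for row in fr) / s for i in range(len(alleles))]
        if corrected:
            hs = nh / (nh - 1) * (1 - msp2 - ho / (2 * nh))
            ht = 1 - sum(x**2 for x in xbar) + hs / (nh * s) - ho / (2 * nh * s)
        else:
            hs = 1 - msp2
            ht = 1 - sum(x**2 for x in xbar)
        ho_l.append(ho)
        hs_l.append(hs)
        ht_l.append(ht)
    Ho, Hs, Ht = (sum(v) / len(v) for v in (ho_l, hs_l, ht_l))
    return 1 - Ho / Hs, (Ht - Hs) / Ht, 1 - Ho / Ht


class TestGlobalFstats:
    def test_identical_populations_uncorrected_fst_zero(self):
        block = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]]
        gm = make_matrix(block + block, ["a"] * 4 + ["b"] * 4)
        res = global_fstats(gm, corrected=False)
        assert res.F_ST == pytest.approx(0.0, abs=1e-12)

    def test_identical_populations_corrected_near_zero(self):
        block = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]]
        gm = make_matrix(block + block, ["a"] * 4 + ["b"] * 4)
        res = global_fstats(gm)
        assert res.F_ST == pytest.approx(0.0, abs=0.1)

    def test_fixed_difference(self):
        gm = make_matrix(
            [[(1, 1)], [(1, 1)], [(2, 2)], [(2, 2)]], ["a", "a", "b", "b"]
        )
        res = global_fstats(gm)
        assert res.H_O == 0.0
        assert res.F_ST == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gm = random_matrix(rng, n_pops=3, n_per_pop=7, n_loci=4, missing_rate=0.05)
        res = global_fstats(gm)
        fis, fst, fit = _fstats_oracle(gm)
        assert res.F_IS == pytest.approx(fis, abs=1e-12)
        assert res.F_ST == pytest.approx(fst, abs=1e-12)
        assert res.F_IT == pytest.approx(fit, abs=1e-12)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(11)
        gm = random_matrix(rng, n_pops=4, n_per_pop=6)
        assert abs(global_fstats(gm).decomposition_residual()) < 1e-12

    def test_monomorphic_flagged(self):
        gm = make_matrix([[(5, 5)], [(5, 5)], [(5, 5)], [(5, 5)]], ["a", "a", "b", "b"])
        res = global_fstats(gm)
        assert np.isnan(res.F_ST)
        assert res.flags

    def test_random_mating_fis_near_zero(self):
        rng = np.random.default_rng(7)
        n = 500
        calls = np.stack(
            [rng.integers(10, 15, size=(n, 3)), rng.integers(10, 15, size=(n, 3))],
            axis=2,
        )
        gm = make_matrix(calls, ["a"] * (n // 2) + ["b"] * (n // 2))
        assert abs(global_fstats(gm).F_IS) < 0.05


class TestHwe:
    def test_all_heterozygotes_yates_hand_value(self):
        # 50 individuals, all 1/2: observed (0, 50, 0) vs expected (12.5, 25, 12.5)
        gm = make_matrix([[(1, 2)]] * 50, ["p1"] * 50)
        res = hwe_tests(gm)
        expected = 2 * (12.0**2 / 12.5) + 24.5**2 / 25.0
        assert res.loc[0, "chi2"] == pytest.approx(expected)
        assert res.loc[0, "df"] == 1

    def test_hw_proportions_not_significant(self):
        # genotype counts exactly at HW for p = q = 0.5: 25 aa, 50 ab, 25 bb
        calls = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        gm = make_matrix(calls, ["p1"] * 100)
        res = hwe_tests(gm)
        assert res.loc[0, "chi2"] < 0.5
        assert not res.loc[0, "significant"]

    def test_monomorphic_is_na(self):
        gm = make_matrix([[(5, 5)]] * 10, ["p1"] * 10)
        assert np.isnan(hwe_tests(gm).loc[0, "chi2"])

    def test_bonferroni_denominator(self, study_like):
        gm, _ = study_like
        res = hwe_tests(gm, alpha=0.05)
        assert res.attrs["n_tests"] == 16 * 15 == 240
        assert len(res) == 240
        assert res.attrs["threshold"] == pytest.approx(0.05 / 240)


class TestLd:
    def test_duplicated_locus_min_p(self):
        rng = np.random.default_rng(3)
        col = rng.integers(10, 14, size=(30, 1, 2))
        calls = np.concatenate([col, col], axis=1)
        gm = make_matrix(calls, ["p1"] * 30)
        res = ld_tests(gm, n_perm=200, seed=0)
        assert res.loc[0, "p"] == pytest.approx(1 / 201)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        gm = random_matrix(rng, n_pops=2, n_per_pop=10, n_loci=3)
        res = ld_tests(gm, n_perm=150, seed=1)
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()

    def test_n_perm_floor(self, two_pop_gm):
        with pytest.raises(ValueError):
            ld_tests(two_pop_gm, n_perm=10)

    def test_null_uniformity(self):
        # independent loci: permutation p-values approximately uniform
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            calls = rng.integers(10, 13, size=(20, 2, 2))
            gm = make_matrix(calls, ["p1"] * 20)
            ps.append(ld_tests(gm, n_perm=100, seed=int(rng.integers(2**31)))["p"][0])
        assert sps.kstest(ps, "uniform").pvalue > 1e-3


class TestNullAlleles:
    def test_equal_he_ho_gives_zero(self):
        # 1/1, 1/2, 1/2, 2/2 x many: Ho = 0.5 and He close; construct exact case
        calls = [[(1, 2)]] * 5 + [[(1, 1)]] * 3 + [[(2, 2)]] * 2
        gm = make_matrix(calls, ["p1"] * 10)
        est = null_allele_estimates(gm).table.iloc[0]
        table = population_diversity(gm).table
        he, ho = table.loc["p1", "H_E"], table.loc["p1", "H_O"]
        assert est["r_chakraborty"] == pytest.approx(max((he - ho) / (he + ho), 0))
        assert est["r_brookfield"] == pytest.approx(max((he - ho) / (1 + he), 0))

    def test_formula_arithmetic(self):
        # direct arithmetic check: He = 0.6, Ho = 0.4
        assert (0.6 - 0.4) / (0.6 + 0.4) == pytest.approx(0.2)
        assert (0.6 - 0.4) / (1 + 0.6) == pytest.approx(0.125)

    def test_negative_clamped(self):
        # excess heterozygosity: Ho > He
        calls = [[(1, 2)]] * 10
        gm = make_matrix(calls, ["p1"] * 10)
        est = null_allele_estimates(gm).table.iloc[0]
        assert est["r_chakraborty"] == 0.0
        assert est["clamped"]

    def test_injected_nulls_recovered(self):
        from msatpop.synth import SynthConfig, generate_study_like, inject_nulls

        gm, _ = generate_study_like(
            SynthConfig(
                seed=11, n_populations=4, sample_sizes=[100] * 4, n_loci=10,
                inbreeding_f=0.0, null_rate_max=0.0, missing_fraction=0.0,
            )
        )
        nulled = inject_nulls(gm, [0.1] * 10, seed=1)
        est = null_allele_estimates(nulled).table
        # Brookfield's estimator targets the true frequency scale
        assert est["r_brookfield"].mean() == pytest.approx(0.1, abs=0.04)


class TestIndividualHet:
    def test_fully_heterozygous(self):
        gm = make_matrix(
            [[(1, 2), (3, 4)], [(1, 1), (3, 3)], [(1, 2), (3, 4)]], ["p1"] * 3
        )
        table = individual_heterozygosity(gm).table
        assert table.loc["ind1", "PHt"] == 1.0
        assert table.loc["ind1", "HL"] == 0.0

    def test_fully_homozygous(self):
        gm = make_matrix(
            [[(1, 2), (3, 4)], [(1, 1), (3, 3)], [(1, 2), (3, 4)]], ["p1"] * 3
        )
        table = individual_heterozygosity(gm).table
        assert table.loc["ind2", "PHt"] == 0.0
        assert table.loc["ind2", "HL"] == 1.0

    def test_hand_evaluated_ir_hl(self):
        # 2 individuals x 3 loci; dataset frequencies computed by hand
        calls = [
            [(1, 1), (3, 4), (5, 5)],
            [(1, 2), (3, 3), (5, 6)],
        ]
        gm = make_matrix(calls, ["p1"] * 2)
        table = individual_heterozygosity(gm).table
        # locus frequencies: L1: f(1)=3/4, f(2)=1/4; L2: f(3)=3/4, f(4)=1/4;
        # L3: f(5)=3/4, f(6)=1/4 -> He = 1 - (9/16 + 1/16) = 6/16 each
        he = 6 / 16
        # ind1: homozygous at L1 (allele 1) and L3 (allele 5); N=3, H=2
        sum_f = 2 * (3 / 4) + 2 * (3 / 4)
        ir = (2 * 2 - sum_f) / (2 * 3 - sum_f)
        assert table.loc["ind1", "IR"] == pytest.approx(ir)
        hl = (he + he) / (he + he + he)
        assert table.loc["ind1", "HL"] == pytest.approx(hl)
        # Hs_exp = PHt / mean He of typed loci
        assert table.loc["ind1", "Hs_exp"] == pytest.approx((1 / 3) / he)

    def test_all_missing_row_is_na(self):
        calls = [[(MISSING, MISSING)], [(1, 2)], [(1, 1)]]
        gm = make_matrix(calls, ["p1"] * 3)
        table = individual_heterozygosity(gm).table
        assert np.isnan(table.loc["ind1", "PHt"])

    def test_bounds(self, study_like):
        gm, _ = study_like
        table = individual_heterozygosity(gm).table.dropna()
        assert ((table["PHt"] >= 0) & (table["PHt"] <= 1)).all()
        assert ((table["HL"] >= 0) & (table["HL"] <= 1)).all()
        assert ((table["IR"] >= -1) & (table["IR"] <= 1)).all()


class TestCompareGroups:
    def test_identical_values_zero_statistic(self):
        res = compare_groups([1.0] * 12, ["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        assert res["kw_chi2"] == 0.0

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(i * 3, 1, 10) for i in range(5)])
        groups = [g for g in "abcde" for _ in range(10)]
        res = compare_groups(values, groups)
        # independent rank-sum evaluation (no ties in continuous data)
        n = len(values)
        ranks = sps.rankdata(values)
        h = 12 / (n * (n + 1)) * sum(
            10 * (ranks[np.array(groups) == g].mean() - (n + 1) / 2) ** 2
            for g in "abcde"
        )
        assert res["kw_chi2"] == pytest.approx(h)
        assert res["df"] == 4

    def test_dunn_detects_shift(self):
        rng = np.random.default_rng(10)
        values = np.concatenate([rng.normal(0, 1, 15), rng.normal(10, 1, 15)])
        res = compare_groups(values, ["a"] * 15 + ["b"] * 15)
        assert res["dunn"]["p_adj"].iloc[0] < 0.001

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["a", "a", "b"])


class TestEvanno:
    def test_linear_likelihood_zero_delta(self):
        loglik = {k: [-100.0 * k + e for e in (0.1, -0.1, 0.05)] for k in range(1, 6)}
        cs = evanno_delta_k(loglik)
        inner = cs.table["delta_k"].iloc[1:-1]
        assert (inner < 3).all()  # second difference ~0 relative to run sd

    def test_breakpoint_detected(self):
        rng = np.random.default_rng(12)
        means = {1: -500.0, 2: -300.0, 3: -290.0, 4: -285.0, 5: -282.0}
        loglik = {k: (means[k] + rng.normal(0, 1, 5)).tolist() for k in means}
        assert evanno_delta_k(loglik).best_k == 2

    def test_boundaries_undefined_and_nonnegative(self):
        loglik = {k: [float(-k * k), float(-k * k) + 0.5] for k in range(1, 5)}
        table = evanno_delta_k(loglik).table
        assert np.isnan(table["delta_k"].iloc[0])
        assert np.isnan(table["delta_k"].iloc[-1])
        assert (table["delta_k"].dropna() >= 0).all()

    def test_zero_sd_flagged(self):
        loglik = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        table = evanno_delta_k(loglik).table
        assert table.loc[2, "zero_sd"]
        assert np.isnan(table.loc[2, "delta_k"])
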