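import numpy as np
import pandas as pd
import pytest

from msatpop.abc import (
    ReferenceTable,
    build_reference_table,
    confusion,
    estimate_params,
    model_choice,
    stats_from_alleles,
    subsample_clusters,
    summary_stats,
)
from msatpop.coalescent import ScenarioSpec, scenario_library

from .conftest import make_matrix, random_matrix


class TestSummaryStats:
    def test_identical_groups_zero_divergence(self):
        rng = np.random.default_rng(0)
        block = rng.integers(10, 15, size=(8, 4, 2))
        sv = stats_from_alleles([block, block.copy()], ["a", "b"])
        d = dict(zip(sv.names, sv.values))
        assert d["Fst_a_b"] == pytest.approx(0.0, abs=1e-12)
        assert d["dmu2_a_b"] == pytest.approx(0.0, abs=1e-12)

    def test_dmu2_fixed_difference(self):
        a = np.full((5, 1, 2), 10)
        b = np.full((5, 1, 2), 20)
        sv = stats_from_alleles([a, b], ["a", "b"])
        assert dict(zip(sv.names, sv.values))["dmu2_a_b"] == pytest.approx(100.0)

    @pytest.mark.parametrize("n_groups", [2, 3, 5])
    def test_vector_length(self, n_groups):
        rng = np.random.default_rng(1)
        blocks = [rng.integers(10, 14, size=(4, 3, 2)) for _ in range(n_groups)]
        sv = stats_from_alleles(blocks, [f"g{i}" for i in range(n_groups)])
        assert len(sv) == 4 * n_groups + 3 * n_groups * (n_groups - 1) // 2

    def test_garza_williamson_bounds(self):
        rng = np.random.default_rng(2)
        blocks = [rng.integers(10, 20, size=(6, 5, 2)) for _ in range(2)]
        sv = stats_from_alleles(blocks, ["a", "b"])
        d = dict(zip(sv.names, sv.values))
        assert 0 < d["M_a"] <= 1.0

    def test_from_genotype_matrix_with_grouping(self):
        rng = np.random.default_rng(3)
        gm = random_matrix(rng, n_pops=4, n_per_pop=5, n_loci=3)
        sv = summary_stats(gm, groups={"pop1": "X", "pop2": "X", "pop3": "Y", "pop4": "Y"})
        assert sv.groups == ["X", "Y"]


def _toy_table(n_per=200, shift=5.0, seed=0, n_stats=4):
    """Reference table with two well-separated synthetic stat clouds."""
    rng = np.random.default_rng(seed)
    lib = scenario_library()
    scen = {"s1": lib["scenario1"], "s2": lib["scenario9"]}
    stats = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_per, n_stats)),
            rng.normal(shift, 1.0, size=(n_per, n_stats)),
        ]
    )
    params = pd.DataFrame(
        {"theta": np.concatenate([rng.uniform(0, 1, n_per), rng.uniform(0, 1, n_per)])}
    )
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    return ReferenceTable(
        scenario_ids=np.array(["s1"] * n_per + ["s2"] * n_per),
        params=params,
        stats=stats,
        stat_names=[f"st{i}" for i in range(n_stats)],
        mad=mad,
        scenarios=scen,
        sample_spec={},
        n_loci=1,
        param_bounds={"theta": (0.0, 1.0)},
    )


class TestModelChoice:
    def test_probabilities_sum_to_one(self):
        table = _toy_table()
        res = model_choice(table, np.zeros(4), tolerance=0.2)
        assert sum(res.direct.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(res.logistic.values()) == pytest.approx(1.0, abs=1e-9)

    def test_separated_clouds_confident(self):
        table = _toy_table()
        res = model_choice(table, np.full(4, 5.0), tolerance=0.25)
        assert res.best() == "s2"
        assert res.logistic["s2"] > 0.9
        # direct and logistic agree on well-separated toys
        assert abs(res.logistic["s2"] - res.direct["s2"]) < 0.15

    def test_observed_point_in_table(self):
        table = _toy_table()
        s_obs = table.stats[10]  # an s1 row
        res = model_choice(table, s_obs, tolerance=0.15)
        assert res.best() == "s1"

    def test_affine_rescaling_invariance(self):
        table = _toy_table()
        s_obs = np.full(4, 1.0)
        base = model_choice(table, s_obs, tolerance=0.2)
        scale = np.array([2.0, 10.0, 0.5, 7.0])
        offset = np.array([1.0, -3.0, 0.0, 100.0])
        stats2 = table.stats * scale + offset
        med = np.median(stats2, axis=0)
        mad = np.median(np.abs(stats2 - med), axis=0)
        table2 = ReferenceTable(
            scenario_ids=table.scenario_ids,
            params=table.params,
            stats=stats2,
            stat_names=table.stat_names,
            mad=mad,
            scenarios=table.scenarios,
            sample_spec={},
            n_loci=1,
        )
        res2 = model_choice(table2, s_obs * scale + offset, tolerance=0.2)
        for k in base.logistic:
            assert res2.logistic[k] == pytest.approx(base.logistic[k], abs=1e-6)

    def test_too_small_tolerance_rejected(self):
        table = _toy_table(n_per=100)
        with pytest.raises(ValueError, match="at least 50"):
            model_choice(table, np.zeros(4), tolerance=0.01)


class TestBuildTable:
    def _mini(self, seed=0, n_per=100):
        lib = scenario_library()
        scen = {k: lib[k] for k in ("scenario1", "scenario9")}
        sample = {p: 4 for p in ("I", "II", "III", "IV", "V")}
        return build_reference_table(scen, n_per, sample, n_loci=5, seed=seed)

    def test_row_counts(self):
        table = self._mini()
        assert len(table) == 200
        assert (table.scenario_ids == "scenario1").sum() == 100

    def test_determinism(self):
        t1 = self._mini(seed=5)
        t2 = self._mini(seed=5)
        assert np.array_equal(t1.stats, t2.stats)
        assert t1.params.equals(t2.params)

    def test_minimum_rows_enforced(self):
        lib = scenario_library()
        with pytest.raises(ValueError):
            build_reference_table(
                {"scenario1": lib["scenario1"]}, 10, {"I": 2}, n_loci=2, seed=0
            )

    def test_csv_round(self, tmp_path):
        table = self._mini()
        table.write_csv(tmp_path / "table.csv")
        df = pd.read_csv(tmp_path / "table.csv")
        assert len(df) == 200
        assert "scenario" in df.columns


class TestEstimateParams:
    def test_constant_parameter_recovered(self):
        table = _toy_table()
        table.params["fixed"] = 7.0
        table.param_bounds["fixed"] = (7.0, 7.0)
        post = estimate_params(table, "s1", np.zeros(4), tolerance=0.5)
        assert post.median("fixed") == 7.0

    def test_quantiles_within_prior(self):
        table = _toy_table()
        post = estimate_params(table, "s1", np.zeros(4), tolerance=0.5)
        lo, hi = post.interval("theta")
        assert 0.0 <= lo <= post.median("theta") <= hi <= 1.0

    def test_informative_stat_shrinks_posterior(self):
        # stats correlated with theta: local-linear adjustment should tighten
        rng = np.random.default_rng(4)
        n = 2000
        theta = rng.uniform(0, 1, n)
        stats = theta[:, None] + rng.normal(0, 0.05, size=(n, 2))
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        lib = scenario_library()
        table = ReferenceTable(
            scenario_ids=np.array(["s1"] * n),
            params=pd.DataFrame({"theta": theta}),
            stats=stats,
            stat_names=["a", "b"],
            mad=mad,
            scenarios={"s1": lib["scenario1"]},
            sample_spec={},
            n_loci=1,
            param_bounds={"theta": (0.0, 1.0)},
        )
        post = estimate_params(table, "s1", np.array([0.5, 0.5]), tolerance=0.1)
        lo, hi = post.interval("theta")
        assert abs(post.median("theta") - 0.5) < 0.05
        assert hi - lo < 0.4


class TestConfusion:
    def test_identical_scenarios_chance_level(self):
        lib = scenario_library()
        # the same generative process under two names: chance accuracy 1/2
        scen = {"x1": lib["scenario9"], "x2": lib["scenario9"]}
        sample = {p: 4 for p in ("I", "II", "III", "IV", "V")}
        table = build_reference_table(scen, 300, sample, n_loci=5, seed=3)
        res = confusion(table, "x1", n_pods=60, tolerance=0.1, seed=4)
        assert 0.25 <= res.type_I <= 0.75
        assert 0.25 <= res.type_II <= 0.75

    def test_default_n_pods_floor(self):
        table = _toy_table()
        with pytest.raises(ValueError):
            confusion(table, "s1", n_pods=10)


class TestSubsample:
    def test_identity_when_k_equals_size(self):
        rng = np.random.default_rng(5)
        gm = random_matrix(rng, n_pops=2, n_per_pop=6)
        out = subsample_clusters(gm, {"pop1": "A", "pop2": "B"}, k=6, seed=0)
        assert out.n_individuals == 12

    def test_k_per_cluster(self):
        rng = np.random.default_rng(6)
        gm = random_matrix(rng, n_pops=4, n_per_pop=30)
        groups = {"pop1": "A", "pop2": "A", "pop3": "B", "pop4": "B"}
        out = subsample_clusters(gm, groups, k=25, seed=1)
        sizes = {p: len(ix) for p, ix in out.population_index().items()}
        assert sizes == {"A": 25, "B": 25}

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        gm = random_matrix(rng, n_pops=2, n_per_pop=40)
        groups = {"pop1": "A", "pop2": "B"}
        a = subsample_clusters(gm, groups, k=10, seed=9)
        b = subsample_clusters(gm, groups, k=10, seed=9)
        assert a.individual_ids == b.individual_ids

    def test_small_cluster_warns_keeps_all(self):
        rng = np.random.default_rng(8)
        gm = random_matrix(rng, n_pops=2, n_per_pop=5)
        with pytest.warns(UserWarning, match="keeping all"):
            out = subsample_clusters(gm, {"pop1": "A", "pop2": "B"}, k=10, seed=0)
        assert out.n_individuals == 10
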