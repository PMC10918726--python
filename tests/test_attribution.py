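"""Variance partitioning, locus attribution, and polygenic climate scores."""

import numpy as np
import pytest

from landgea import (
    LocusAttribution,
    assign_strongest_variable,
    fit_score_models,
    marginal_climate_effects,
    partition_variance,
    polygenic_scores,
)
from landgea.scan import CandidateSet
import pandas as pd


def brute_force_r2(y, x):
    yc = y - y.mean(0)
    xc = x - x.mean(0)
    hat = xc @ np.linalg.inv(xc.T @ xc) @ xc.T
    return float(((hat @ yc) ** 2).sum() / (yc**2).sum())


class TestPartitionVariance:
    def test_additivity_and_projection_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(12, 40))
        c = rng.normal(size=(12, 3))
        s = rng.normal(size=(12, 4))
        part = partition_variance(y, c, s, n_perm=99, seed=0)
        both = np.column_stack([c, s])
        r2_c, r2_s, r2_b = (brute_force_r2(y, m) for m in (c, s, both))
        assert part.total == pytest.approx(r2_b, abs=1e-8)
        assert part.exclusive_climate == pytest.approx(r2_b - r2_s, abs=1e-8)
        assert part.exclusive_structure == pytest.approx(r2_b - r2_c, abs=1e-8)
        assert part.joint == pytest.approx(r2_c + r2_s - r2_b, abs=1e-8)
        # exact additivity
        total = part.exclusive_climate + part.exclusive_structure + part.joint
        assert total == pytest.approx(part.total, abs=1e-10)
        assert part.unexplained == pytest.approx(1 - part.total, abs=1e-12)
        adj_sum = (part.exclusive_climate_adj + part.exclusive_structure_adj
                   + part.joint_adj)
        assert adj_sum == pytest.approx(part.total_adj, abs=1e-6)

    def test_orthogonal_predictors_no_joint_component(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(12, 6)))
        c, s = q[:, :3], q[:, 3:6]           # exactly orthogonal blocks
        y = rng.normal(size=(12, 30))
        part = partition_variance(y, c, s, n_perm=99, seed=0)
        assert abs(part.joint) < 0.02

    def test_identical_predictors_all_joint(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 30))
        with pytest.warns(UserWarning, match="collinear"):
            part = partition_variance(y, c, c.copy(), n_perm=99, seed=0)
        assert abs(part.exclusive_climate) < 1e-10
        assert abs(part.exclusive_structure) < 1e-10
        assert part.joint == pytest.approx(part.total, abs=1e-10)

    def test_too_many_predictors_errors(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="fewer"):
            partition_variance(rng.normal(size=(8, 10)),
                               rng.normal(size=(8, 4)),
                               rng.normal(size=(8, 4)), n_perm=99)


class TestMarginalEffects:
    def test_duplicated_variable_has_no_marginal_effect(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=(12, 3))
        c = np.column_stack([c, c[:, 0]])     # v3 duplicates v0
        y = rng.normal(size=(12, 20))
        with pytest.warns(UserWarning, match="collinear"):
            df = marginal_climate_effects(y, c, list("abcd"), None, n_perm=99)
        assert abs(df.loc[df.variable == "a", "r2"].iloc[0]) < 1e-10
        assert abs(df.loc[df.variable == "d", "r2"].iloc[0]) < 1e-10

    def test_driving_variable_has_largest_marginal_effect(self):
        from landgea import SimConfig, simulate_metapopulation, \
            population_allele_frequencies

        wins = 0
        for seed in range(10):
            cfg = SimConfig(n_pops=12, n_ind_per_pop=20, n_loci=300,
                            n_selected=60, beta=2.0, tree="star", drift_F=0.1,
                            seed=seed)
            g, clim, truth = simulate_metapopulation(cfg)
            f = population_allele_frequencies(g)
            sel = np.isin(np.array(f.locus_ids), truth.selected_locus_ids)
            df = marginal_climate_effects(
                f.subset_loci(sel), clim.standardized(),
                clim.valid_variables(), None, n_perm=99, seed=seed)
            wins += df.loc[df.adj_r2.idxmax(), "variable"] == "clim1"
        assert wins >= 9

    def test_null_marginal_p_not_degenerate(self):
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(30):
            y = rng.normal(size=(12, 15))
            c = rng.normal(size=(12, 3))
            df = marginal_climate_effects(y, c, list("abc"), None,
                                          n_perm=99, seed=rep)
            ps.extend(df.p.tolist())
        ps = np.asarray(ps)
        assert 0.2 < ps.mean() < 0.8          # roughly uniform, not stuck


class TestAssignStrongestVariable:
    def test_tie_breaks_to_first_variable(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(10, 8))
        v = rng.normal(size=(10, 1))
        c = np.column_stack([v, v])           # identical variables -> ties
        with pytest.warns(UserWarning, match="collinear"):
            la = assign_strongest_variable(y, c, ["first", "second"], None)
        assert set(la.assigned) == {"first"}

    def test_normalized_scores_standardized(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(12, 50))
        c = rng.normal(size=(12, 3))
        la = assign_strongest_variable(y, c, list("abc"), None)
        np.testing.assert_allclose(la.scores.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(la.scores.std(axis=0), 1, atol=1e-10)
        assert all(la.assigned[j] == la.variables[np.abs(la.scores[j]).argmax()]
                   for j in range(50))

    def test_single_locus_flagged_unreliable(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(10, 1))
        c = rng.normal(size=(10, 2))
        with pytest.warns(UserWarning, match="unreliable"):
            la = assign_strongest_variable(y, c, list("ab"), None)
        assert not la.reliable
        np.testing.assert_allclose(la.scores, 0)

    def test_recovers_single_driver_above_chance(self):
        from landgea import (SimConfig, population_allele_frequencies,
                             simulate_metapopulation)
        from scipy import stats as sps

        cfg = SimConfig(n_pops=12, n_ind_per_pop=12, n_loci=400,
                        n_selected=40, beta=2.0, tree="star", drift_F=0.1,
                        seed=23)
        g, clim, truth = simulate_metapopulation(cfg)
        f = population_allele_frequencies(g)
        la = assign_strongest_variable(f, clim.standardized(),
                                       clim.valid_variables(), None)
        sel = np.isin(np.array(la.locus_ids), truth.selected_locus_ids)
        correct = int((np.array(la.assigned)[sel] == "clim1").sum())
        n = int(sel.sum())
        assert sps.binomtest(correct, n, 1 / 5, alternative="greater").pvalue < 0.01


def make_candidates(ids, methods=("a", "b")):
    return CandidateSet(
        locus_ids=list(ids),
        support={l: len(methods) for l in ids},
        methods_of={l: list(methods) for l in ids},
        min_methods=2,
        overlap=pd.DataFrame(),
    )


class TestPolygenicScores:
    def setup_small(self, small_sim):
        from landgea import population_allele_frequencies

        g, clim, truth = small_sim
        f = population_allele_frequencies(g)
        ids = truth.selected_locus_ids[:6]
        cand = make_candidates(ids)
        la = LocusAttribution(
            locus_ids=ids, assigned=["clim1"] * len(ids),
            scores=np.zeros((len(ids), len(clim.variables))),
            variables=clim.valid_variables())
        return g, clim, f, cand, la

    def test_direct_sum(self):
        from landgea import GenotypeMatrix, LocusInfo, ClimateTable, \
            FrequencyTable

        env = np.array([0.0, 1.0, 2.0])
        clim = ClimateTable(env[:, None], ["v"], ["a", "b", "c"],
                            np.zeros(3), np.array([1.0, 2.0, 3.0]))
        # frequencies rising with env at all 3 loci -> positive orientation
        freqs = np.array([[0.1] * 3, [0.5] * 3, [0.9] * 3])
        f = FrequencyTable(freqs, np.full((3, 3), 20), ["a", "b", "c"],
                           ["L0", "L1", "L2"])
        geno = np.array([[2, 2, 1]])
        g = GenotypeMatrix(
            geno, ["i1"], {"i1": "a"},
            [LocusInfo("1", j + 1, f"L{j}", "A", "T") for j in range(3)])
        cand = make_candidates(["L0", "L1", "L2"])
        la = LocusAttribution(["L0", "L1", "L2"], ["v"] * 3,
                              np.zeros((3, 1)), ["v"])
        res = polygenic_scores(g, cand, la, f, clim, fit_models=False)
        assert res.scores["v"][0] == 5

    def test_sign_flip_symmetry(self, small_sim):
        g, clim, f, cand, la = self.setup_small(small_sim)
        res = polygenic_scores(g, cand, la, f, clim, fit_models=False)
        flipped = ClimateTableFlip(clim)
        res2 = polygenic_scores(g, cand, la, f, flipped, fit_models=False)
        m = len(cand.locus_ids)
        np.testing.assert_array_equal(res2.scores["clim1"],
                                      2 * m - res.scores["clim1"])

    def test_positive_scaling_invariance(self, small_sim):
        g, clim, f, cand, la = self.setup_small(small_sim)
        res = polygenic_scores(g, cand, la, f, clim, fit_models=False)
        from landgea import ClimateTable

        scaled = ClimateTable(clim.values * 3.7, clim.variables,
                              clim.populations, clim.longitude, clim.latitude)
        res2 = polygenic_scores(g, cand, la, f, scaled, fit_models=False)
        np.testing.assert_array_equal(res.scores["clim1"], res2.scores["clim1"])

    def test_identical_genotypes_equal_scores(self):
        from landgea import GenotypeMatrix, LocusInfo, ClimateTable, \
            FrequencyTable

        env = np.array([0.0, 1.0])
        clim = ClimateTable(env[:, None], ["v"], ["a", "b"],
                            np.zeros(2), np.array([1.0, 2.0]))
        freqs = np.array([[0.2, 0.3], [0.7, 0.8]])
        f = FrequencyTable(freqs, np.full((2, 2), 20), ["a", "b"],
                           ["L0", "L1"])
        geno = np.array([[1, 1], [1, 1], [1, 1]])
        g = GenotypeMatrix(
            geno, ["i1", "i2", "i3"], {"i1": "a", "i2": "a", "i3": "b"},
            [LocusInfo("1", j + 1, f"L{j}", "A", "T") for j in range(2)])
        cand = make_candidates(["L0", "L1"])
        la = LocusAttribution(["L0", "L1"], ["v", "v"], np.zeros((2, 1)), ["v"])
        res = polygenic_scores(g, cand, la, f, clim, fit_models=False)
        assert len(set(res.scores["v"].tolist())) == 1

    def test_score_bounds(self, small_sim):
        g, clim, f, cand, la = self.setup_small(small_sim)
        res = polygenic_scores(g, cand, la, f, clim, fit_models=False)
        m = len(cand.locus_ids)
        s = res.scores["clim1"]
        assert (s >= 0).all() and (s <= 2 * m).all()


class ClimateTableFlip:
    """Climate table proxy with every variable negated."""

    def __init__(self, base):
        self.values = -base.values
        self.variables = base.variables
        self.populations = base.populations
        self.longitude = base.longitude
        self.latitude = base.latitude


class TestFitScoreModels:
    def test_linear_data_selects_linear(self):
        rng = np.random.default_rng(0)
        env = rng.normal(size=60)
        scores = 3 + 2 * env + rng.normal(0, 0.1, 60)
        fit = fit_score_models(scores, env)
        assert fit.selected == "linear"
        assert fit.aic_quadratic - fit.aic_linear > -2

    def test_quadratic_data_selects_quadratic(self):
        rng = np.random.default_rng(1)
        env = np.linspace(-2, 2, 50)
        scores = 1 + env - 3 * env**2 + rng.normal(0, 0.2, 50)
        fit = fit_score_models(scores, env)
        assert fit.selected == "quadratic"
        assert fit.adj_r2 > 0.9

    def test_few_distinct_env_values_skips_quadratic(self):
        env = np.array([0.0, 1.0] * 10)
        scores = env * 2 + 1
        with pytest.warns(UserWarning, match="quadratic"):
            fit = fit_score_models(scores, env)
        assert fit.selected == "linear"
        assert fit.aic_quadratic is None
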