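"""RDA machinery, the three GEA scans, and consensus calling."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from landgea import (
    FrequencyTable,
    consensus_candidates,
    covariance_scan,
    estimate_pop_covariance,
    fit_rda,
    latent_factor_scan,
    permutation_anova,
    rda_outliers,
)
from landgea.scan import OutlierSet, RDAResult
from conftest import make_genotypes


def brute_force_rda(y, x):
    """Explicit hat-matrix projection + full eigendecomposition oracle."""
    yc = y - y.mean(0)
    xc = x - x.mean(0)
    hat = xc @ np.linalg.inv(xc.T @ xc) @ xc.T
    fitted = hat @ yc
    n = y.shape[0]
    eig = np.linalg.eigvalsh(fitted.T @ fitted / (n - 1))[::-1]
    r2 = (fitted**2).sum() / (yc**2).sum()
    return eig, r2, fitted


class TestFitRda:
    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(12, 50))
        x = rng.normal(size=(12, 3))
        res = fit_rda(y, x)
        eig_o, r2_o, fitted = brute_force_rda(y, x)
        np.testing.assert_allclose(res.eigenvalues, eig_o[:3], atol=1e-8)
        assert res.r2 == pytest.approx(r2_o, abs=1e-10)
        # locus scores span the fitted-value row space
        recon = res.locus_scores / np.sqrt(res.eigenvalues)
        np.testing.assert_allclose(recon.T @ recon, np.eye(3), atol=1e-8)

    def test_single_column_degenerates_to_regression(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 1))
        y = (2 * x[:, 0] + rng.normal(size=15))[:, None]
        res = fit_rda(y, x)
        r = np.corrcoef(y[:, 0], x[:, 0])[0, 1]
        assert res.r2 == pytest.approx(r**2, abs=1e-12)

    def test_ezekiel_adjustment(self):
        # r2=0.5, n=12, p=5 -> adj = 1 - 0.5*11/6 ~ 0.0833
        rng = np.random.default_rng(2)
        y = rng.normal(size=(12, 30))
        x = rng.normal(size=(12, 5))
        res = fit_rda(y, x)
        expect = 1 - (1 - res.r2) * 11 / 6
        assert res.adj_r2 == pytest.approx(expect, abs=1e-12)
        assert 1 - (1 - 0.5) * 11 / 6 == pytest.approx(0.0833, abs=5e-5)

    def test_partial_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = rng.normal(size=(12, 20))
            x = rng.normal(size=(12, 3))
            z = rng.normal(size=(12, 2))
            direct = fit_rda(y, x, z)
            zc = z - z.mean(0)
            hz = zc @ np.linalg.pinv(zc)
            yc = y - y.mean(0)
            xc = x - x.mean(0)
            manual = fit_rda(yc - hz @ yc, xc - hz @ xc)
            np.testing.assert_allclose(direct.eigenvalues, manual.eigenvalues,
                                       atol=1e-10)
            assert direct.r2 == pytest.approx(manual.r2, abs=1e-10)

    def test_variance_conservation(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(10, 25))
        x = rng.normal(size=(10, 4))
        res = fit_rda(y, x)
        assert res.constrained_variance + res.residual_variance == pytest.approx(
            res.total_variance, abs=1e-10)

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 2))
        x = np.column_stack([x, x[:, 0] + x[:, 1]])
        y = rng.normal(size=(12, 8))
        with pytest.warns(UserWarning, match="collinear"):
            res = fit_rda(y, x)
        assert res.n_predictors == 2

    def test_too_many_predictors_error(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="rows"):
            fit_rda(rng.normal(size=(5, 10)), rng.normal(size=(5, 6)))

    def test_matches_vegan_rda(self, tmp_path):
        """Independent oracle: R vegan's rda() on the same small instance."""
        rng = np.random.default_rng(7)
        y = rng.normal(size=(12, 15))
        x = rng.normal(size=(12, 3))
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            y <- as.matrix(read.csv("y.csv", header=FALSE))
            x <- as.data.frame(read.csv("x.csv", header=FALSE))
            m <- rda(y ~ ., data=x)
            cat(m$CCA$eig, sep="\\n")
            cat(m$CCA$tot.chi / m$tot.chi, "\\n")
        """)
        (tmp_path / "oracle.R").write_text(script)
        try:
            out = subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path,
                                 capture_output=True, text=True, timeout=120)
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        if out.returncode != 0:
            pytest.skip(f"vegan oracle failed: {out.stderr[:200]}")
        vals = [float(v) for v in out.stdout.split()]
        eig_ref, r2_ref = np.array(vals[:3]), vals[3]
        res = fit_rda(y, x)
        np.testing.assert_allclose(res.eigenvalues, eig_ref, rtol=1e-5)
        assert res.r2 == pytest.approx(r2_ref, rel=1e-5)


class TestPermutationAnova:
    def test_perfect_fit_minimal_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 2))
        y = x @ rng.normal(size=(2, 10))        # exact linear function
        p, _ = permutation_anova(y, x, n_perm=199, seed=1)
        assert p == pytest.approx(1 / 200)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        y, x = rng.normal(size=(10, 8)), rng.normal(size=(10, 2))
        p1, _ = permutation_anova(y, x, n_perm=199, seed=3)
        p2, _ = permutation_anova(y, x, n_perm=199, seed=3)
        assert p1 == p2

    def test_conditioned_null_is_not_significant(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(14, 2))
        y = z @ rng.normal(size=(2, 12)) + 0.1 * rng.normal(size=(14, 12))
        x = rng.normal(size=(14, 2))            # pure noise given z
        p, _ = permutation_anova(y, x, z, n_perm=199, seed=5)
        assert p > 0.05

    def test_per_axis_pvalues_returned(self):
        rng = np.random.default_rng(3)
        y, x = rng.normal(size=(12, 9)), rng.normal(size=(12, 3))
        p, ax = permutation_anova(y, x, n_perm=99, seed=0, per_axis=True)
        assert ax is not None and ax.shape == (3,)
        assert ((ax >= 1 / 100) & (ax <= 1.0)).all()


class TestRdaOutliers:
    def make_result(self, scores):
        scores = np.asarray(scores, float)
        k = scores.shape[1]
        return RDAResult(
            eigenvalues=np.ones(k), site_scores=np.zeros((5, k)),
            locus_scores=scores, biplot_scores=np.zeros((1, k)),
            r2=0.5, adj_r2=0.4, total_variance=1.0, constrained_variance=0.5,
            residual_variance=0.5, n_rows=5, n_predictors=1,
            locus_ids=[f"L{j}" for j in range(scores.shape[0])])

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(0)
        res = self.make_result(rng.normal(size=(100_000, 1)))
        out = rda_outliers(res, 1, 3.0)
        assert len(out) / 100_000 == pytest.approx(0.0027, abs=0.0005)

    def test_sd_zero_flags_everything(self):
        rng = np.random.default_rng(1)
        res = self.make_result(rng.normal(size=(50, 1)))
        assert len(rda_outliers(res, 1, 0.0)) == 50

    def test_single_extreme_locus(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(200, 1))
        scores[17] = 10.0
        out = rda_outliers(self.make_result(scores), 1, 3.0)
        assert out.locus_ids == ["L17"]

    def test_too_many_axes_error(self):
        res = self.make_result(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="axes"):
            rda_outliers(res, 3, 3.0)


class TestLatentFactorScan:
    def test_env_equal_locus_flagged_without_correction(self):
        rng = np.random.default_rng(0)
        env = rng.normal(size=40)
        geno = rng.integers(0, 3, size=(40, 30))
        geno[:, 5] = (env > np.quantile(env, 1 / 3)).astype(int) + \
                     (env > np.quantile(env, 2 / 3)).astype(int)
        g = make_genotypes(geno)
        with pytest.warns(UserWarning, match="k=0"):
            res = latent_factor_scan(g, env, k=0)
        assert res.outlier[5]
        assert res.p[5] < 1e-6

    def test_duplicated_locus_identical_statistic(self):
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(30, 10))
        geno[:, 7] = geno[:, 3]
        res = latent_factor_scan(make_genotypes(geno), rng.normal(size=30), k=2)
        assert res.statistic[3] == pytest.approx(res.statistic[7], abs=1e-12)

    def test_constant_env_errors(self):
        g = make_genotypes(np.random.default_rng(2).integers(0, 3, (10, 5)))
        with pytest.raises(ValueError, match="constant"):
            latent_factor_scan(g, np.ones(10), k=2)

    def test_lambda_decreases_toward_one_with_k(self, null_sim):
        """Structured null: svd-mode inflation shrinks as factors span structure."""
        g, clim, _ = null_sim
        pop_index = {p: i for i, p in enumerate(clim.populations)}
        ind_pop = np.array([pop_index[g.population_of[i]]
                            for i in g.individual_ids])
        env = clim.values[ind_pop, 0]
        lams = [latent_factor_scan(g, env, k=k, factor_mode="svd").inflation_lambda
                for k in (0, 3, 6, 7)]        # 8 pops -> 7 structure dims
        assert lams[0] > lams[1] > lams[2] > lams[3]
        assert 0.8 <= lams[3] <= 1.2

    def test_env_orthogonal_mode_retains_population_signal(self, small_sim):
        g, clim, truth = small_sim
        pop_index = {p: i for i, p in enumerate(clim.populations)}
        ind_pop = np.array([pop_index[g.population_of[i]]
                            for i in g.individual_ids])
        env = clim.values[ind_pop, 0]
        res = latent_factor_scan(g, env, k=g.populations.__len__() - 1)
        sel = np.isin(np.array(g.locus_ids()), truth.selected_locus_ids)
        assert np.median(np.abs(res.statistic[sel])) > \
               2 * np.median(np.abs(res.statistic[~sel]))


class TestCovarianceScan:
    def test_identity_omega_equals_ols(self):
        rng = np.random.default_rng(0)
        k, L = 10, 40
        freqs = rng.uniform(0.2, 0.8, size=(k, L))
        f = FrequencyTable(freqs, np.full((k, L), 48), [f"p{i}" for i in range(k)],
                           [f"L{j}" for j in range(L)])
        env = rng.normal(size=k)
        from landgea.scan import PopCovariance, _standardize_freqs

        omega = PopCovariance(np.eye(k), f.populations, 0.0, L)
        res = covariance_scan(f, env, omega, outlier_rule="bh")
        # direct OLS oracle per locus
        y, _ = _standardize_freqs(freqs)
        x = np.column_stack([np.ones(k), (env - env.mean()) / env.std()])
        for j in rng.choice(L, 5, replace=False):
            b, res_, *_ = np.linalg.lstsq(x, y[:, j], rcond=None)[:2]
            sigma2 = res_[0] / (k - 2)
            se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
            assert res.statistic[j] == pytest.approx(b[1] / se, rel=1e-9)

    def test_exact_linear_locus_flagged(self):
        rng = np.random.default_rng(1)
        k, L = 12, 60
        env = rng.normal(size=k)
        freqs = rng.uniform(0.3, 0.7, size=(k, L))
        z = (env - env.mean()) / env.std()
        freqs[:, 0] = 0.5 + 0.15 * np.clip(z, -3, 3)   # exact linear response
        f = FrequencyTable(freqs, np.full((k, L), 48),
                           [f"p{i}" for i in range(k)],
                           [f"L{j}" for j in range(L)])
        from landgea.scan import PopCovariance

        omega = PopCovariance(np.eye(k), f.populations, 0.0, L)
        res = covariance_scan(f, env, omega)
        assert res.outlier[0]
        assert res.p[0] < 1e-10

    def test_recovers_selected_ranks(self, small_sim):
        g, clim, truth = small_sim
        from landgea import apply_variant_filters, population_allele_frequencies

        g2, _ = apply_variant_filters(g, 0.05, 0)
        f = population_allele_frequencies(g2)
        sel = np.isin(np.array(f.locus_ids), truth.selected_locus_ids)
        omega = estimate_pop_covariance(f, neutral_loci=~sel)
        res = covariance_scan(f, clim.values[:, 0], omega)
        ranks = stats.rankdata(-np.abs(res.statistic))
        assert np.median(ranks[sel]) < 0.1 * f.n_loci


class TestPopCovariance:
    def test_identical_populations_regularized_invertible(self):
        freqs = np.tile(np.random.default_rng(0).uniform(0.2, 0.8, 30), (5, 1))
        f = FrequencyTable(freqs, np.full((5, 30), 40),
                           [f"p{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="neutral loci"):
            omega = estimate_pop_covariance(f)
        np.linalg.cholesky(omega.omega)      # must not raise

    def test_epsilon_zero_equals_sample_covariance(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.1, 0.9, size=(6, 200))
        f = FrequencyTable(freqs, np.full((6, 200), 40),
                           [f"p{i}" for i in range(6)])
        omega = estimate_pop_covariance(f, epsilon=0.0)
        from landgea.scan import _standardize_freqs

        x, usable = _standardize_freqs(freqs)
        expect = x[:, usable] @ x[:, usable].T / (usable.sum() - 1)
        np.testing.assert_allclose(omega.omega, expect, atol=1e-12)

    def test_star_tree_covariance_near_exchangeable(self):
        from landgea import SimConfig, simulate_metapopulation, \
            population_allele_frequencies

        cfg = SimConfig(n_pops=8, n_ind_per_pop=20, n_loci=5000, n_selected=0,
                        tree="star", drift_F=0.1, missing_rate=0.0, fis=0.0,
                        seed=19)
        g, _, _ = simulate_metapopulation(cfg)
        f = population_allele_frequencies(g)
        omega = estimate_pop_covariance(f).omega
        diag = np.diag(omega)
        off = omega[~np.eye(8, dtype=bool)]
        assert diag.std() / diag.mean() < 0.3
        assert off.std() / abs(off.mean()) < 0.3


class TestConsensus:
    def s(self, name, ids):
        return OutlierSet(name, list(ids), "")

    def test_two_method_rule(self):
        cand = consensus_candidates(
            [self.s("a", ["l1", "l2"]), self.s("b", ["l2", "l3"]),
             self.s("c", ["l3"])], 2)
        assert cand.locus_ids == ["l2", "l3"]
        assert cand.support == {"l2": 2, "l3": 2}

    def test_disjoint_sets_empty(self):
        cand = consensus_candidates([self.s("a", ["l1"]), self.s("b", ["l2"])], 2)
        assert len(cand) == 0

    def test_identical_sets_full_support(self):
        ids = ["l1", "l2", "l3"]
        cand = consensus_candidates([self.s(m, ids) for m in "abc"], 2)
        assert cand.locus_ids == ids
        assert all(v == 3 for v in cand.support.values())

    def test_overlap_fractions(self):
        cand = consensus_candidates(
            [self.s("a", ["l1", "l2", "l3"]), self.s("b", ["l2", "l3", "l4"])], 2)
        row = cand.overlap.iloc[0]
        assert row["jaccard"] == pytest.approx(2 / 4)
        assert row["frac_of_a"] == pytest.approx(2 / 3)
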