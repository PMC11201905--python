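"""ST/MT-GBLUP solutions, bivariate REML, bending, derived parameters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from multigp import gblup, genostats, simdata
from multigp.genostats import GRM


def toy_grm(n, m, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    # ensure polymorphism
    d[0] = 1.0
    p = d.mean(axis=0) / 2
    Z = d - 2 * p
    denom = 2 * np.sum(p * (1 - p))
    ids = [f"i{k}" for k in range(n)]
    return GRM(G=Z @ Z.T / denom, freqs=p, denom=denom, individuals=ids), d, ids


class TestStGblup:
    def test_constant_response_shrinks_to_zero(self):
        grm, _, ids = toy_grm(40, 80, seed=1)
        y = pd.Series(np.full(40, 3.14), index=ids)
        fit = gblup.fit_st_gblup(y, grm)
        assert fit.vc[0] < 1e-4
        assert np.abs(fit.a_hat.to_numpy()).max() < 1e-3

    def test_fixed_vc_matches_dense_mme(self):
        """6-individual toy at fixed variances equals the direct dense solve of
        [1'V^-1 1] mu = 1'V^-1 y and a = s_a G V^-1 (y - mu)."""
        grm, _, ids = toy_grm(6, 30, seed=2)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(size=6), index=ids)
        sa2, se2 = 1.3, 2.1
        fit = gblup.fit_st_gblup(y, grm, vc=(sa2, se2))
        G = grm.G + 1e-6 * np.eye(6)
        V = sa2 * G + se2 * np.eye(6)
        Vi = np.linalg.inv(V)
        one = np.ones(6)
        mu = (one @ Vi @ y.to_numpy()) / (one @ Vi @ one)
        a = sa2 * grm.G @ Vi @ (y.to_numpy() - mu)
        assert fit.mu.iloc[0] == pytest.approx(mu, abs=1e-10)
        np.testing.assert_allclose(fit.a_hat.to_numpy(), a, atol=1e-8)

    def test_equals_snp_blup_ridge(self):
        """GBLUP predictions equal ridge regression on centered dosages with
        lambda = s_e * denom / s_a (the SNP-BLUP equivalence)."""
        grm, d, ids = toy_grm(60, 120, seed=4)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=60), index=ids)
        sa2, se2 = 1.0, 2.0
        fit = gblup.fit_st_gblup(y, grm, vc=(sa2, se2))
        Z = d - 2 * (d.mean(axis=0) / 2)
        lam = se2 * grm.denom / sa2
        yc = y.to_numpy() - float(fit.mu.iloc[0])
        g_hat = np.linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ yc)
        pred = Z @ g_hat
        # the 1e-6 G stabilizer perturbs solutions at ~1e-6; correlation is the
        # cleaner equivalence statement
        assert np.corrcoef(pred, fit.a_hat.to_numpy())[0, 1] > 0.999999

    def test_mean_shift_invariance(self):
        grm, _, ids = toy_grm(30, 60, seed=6)
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=30), index=ids)
        f1 = gblup.fit_st_gblup(y, grm, vc=(1.0, 1.0))
        f2 = gblup.fit_st_gblup(y + 57.0, grm, vc=(1.0, 1.0))
        np.testing.assert_allclose(f1.a_hat.to_numpy(), f2.a_hat.to_numpy(), atol=1e-8)
        assert f2.mu.iloc[0] - f1.mu.iloc[0] == pytest.approx(57.0, abs=1e-8)

    def test_validation_predictions_through_off_diagonal_blocks(self):
        grm, _, ids = toy_grm(50, 100, seed=8)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(size=40), index=ids[:40])
        fit = gblup.fit_st_gblup(y, grm, vc=(1.0, 1.0))
        assert set(fit.a_hat.index) == set(ids)
        assert np.isfinite(fit.a_hat.loc[ids[40:]].to_numpy()).all()


class TestMtGblup:
    def _two_pop(self, n=30, seed=10):
        grm, d, ids = toy_grm(2 * n, 150, seed=seed)
        pop = pd.Series(["A"] * n + ["B"] * n, index=ids)
        rng = np.random.default_rng(seed + 1)
        y = pd.Series(rng.normal(size=2 * n), index=ids)
        return grm, pop, y

    def test_diagonal_m_equals_per_population_st(self):
        grm, pop, y = self._two_pop()
        vc = gblup.MultiTraitVC(M=np.diag([1.2, 0.8]), R=np.diag([2.0, 1.5]),
                                labels=["A", "B"])
        mt = gblup.fit_mt_gblup(y, pop, grm, vc)
        for lab, sa2, se2 in (("A", 1.2, 2.0), ("B", 0.8, 1.5)):
            ids_p = [i for i in y.index if pop[i] == lab]
            sub_idx = grm.index(ids_p)
            sub = GRM(G=grm.G[np.ix_(sub_idx, sub_idx)], freqs=grm.freqs,
                      denom=grm.denom, individuals=ids_p)
            st_fit = gblup.fit_st_gblup(y.loc[ids_p], sub, vc=(sa2, se2))
            a_mt = mt.a_hat.loc[ids_p].to_numpy()
            a_st = st_fit.a_hat.loc[ids_p].to_numpy()
            np.testing.assert_allclose(a_mt, a_st, rtol=1e-8, atol=1e-10)

    def test_information_flows_with_perfect_correlation(self):
        grm, pop, y = self._two_pop(seed=12)
        M = np.array([[1.0, 0.999], [0.999, 1.0]])
        vc = gblup.MultiTraitVC(M=M, R=np.diag([1.0, 1.0]), labels=["A", "B"])
        fit1 = gblup.fit_mt_gblup(y, pop, grm, vc)
        y2 = y.copy()
        ids_b = [i for i in y.index if pop[i] == "B"]
        y2.loc[ids_b] = y.loc[ids_b].to_numpy()[::-1]
        fit2 = gblup.fit_mt_gblup(y2, pop, grm, vc)
        ids_a = [i for i in y.index if pop[i] == "A"]
        assert not np.allclose(fit1.a_hat.loc[ids_a], fit2.a_hat.loc[ids_a])

    def test_toy_matches_dense_gls_solve(self):
        """8 individuals, 2 traits: predictions equal the hand-assembled
        covariance solve Cov(a, y) V^-1 (y - X mu)."""
        grm, d, ids = toy_grm(8, 40, seed=13)
        pop = pd.Series(["A"] * 4 + ["B"] * 4, index=ids)
        rng = np.random.default_rng(14)
        y = pd.Series(rng.normal(size=8), index=ids)
        M = np.array([[1.5, 0.6], [0.6, 1.0]])
        R = np.diag([2.0, 1.0])
        vc = gblup.MultiTraitVC(M=M, R=R, labels=["A", "B"])
        fit = gblup.fit_mt_gblup(y, pop, grm, vc)
        tr = np.array([0] * 4 + [1] * 4)
        G = grm.G + 1e-6 * np.eye(8)
        V = M[np.ix_(tr, tr)] * G + np.diag(np.diag(R)[tr])
        X = np.zeros((8, 2)); X[np.arange(8), tr] = 1
        Vi = np.linalg.inv(V)
        mu = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy())
        C = M[np.ix_(tr, tr)] * grm.G
        a = C @ Vi @ (y.to_numpy() - X @ mu)
        np.testing.assert_allclose(fit.mu.to_numpy(), mu, atol=1e-10)
        np.testing.assert_allclose(fit.a_hat.to_numpy(), a, atol=1e-8)

    def test_rejects_indefinite_m(self):
        grm, pop, y = self._two_pop(seed=15)
        vc = object.__new__(gblup.MultiTraitVC)   # bypass constructor checks
        vc.M = np.array([[1.0, 1.2], [1.2, 1.0]])
        vc.R = np.diag([1.0, 1.0])
        vc.labels = ["A", "B"]
        with pytest.raises(ValueError, match="bend"):
            gblup.fit_mt_gblup(y, pop, grm, vc)


class TestPairwiseVc:
    def test_null_and_strong_correlation_recovery(self):
        sim = simdata.simulate(simdata.SimulationConfig(
            n_per_pop=250, n_snp=800, n_qtl=200, founder_haplotypes=200,
            genetic_corr=np.array([[1.0, 0.0], [0.0, 1.0]]), seed=31))
        gs = genostats.mean_impute(genostats.qc_filter(sim.genotypes))
        grm = genostats.vanraden_g(gs)
        rng = np.random.default_rng(32)
        bv = sim.state.true_bv.loc[gs.individuals]
        # high-reliability response isolates the estimator from phenotype noise
        y = pd.Series(bv.to_numpy() + rng.normal(0, 0.1 * bv.std(), len(bv)),
                      index=gs.individuals)
        pop = pd.Series(gs.population, index=gs.individuals)
        res = gblup.estimate_pairwise_vc(y, pop, grm, "pop1", "pop2")
        assert abs(res["correlation"]) < 0.2

    def test_split_population_estimates_high_correlation(self):
        """The same architecture split at random in two halves behaves like
        genetic correlation ~1."""
        sim = simdata.simulate(simdata.SimulationConfig(
            n_populations=1, n_per_pop=400, n_snp=800, n_qtl=200,
            founder_haplotypes=300, seed=33))
        gs = genostats.mean_impute(genostats.qc_filter(sim.genotypes))
        grm = genostats.vanraden_g(gs)
        rng = np.random.default_rng(34)
        bv = sim.state.true_bv.loc[gs.individuals]
        # h2 = 0.3 on the y_c scale
        y = pd.Series(bv.to_numpy() + rng.normal(0, np.sqrt(bv.var() * 7 / 3), len(bv)),
                      index=gs.individuals)
        half = rng.permutation(len(y)) < len(y) // 2
        pop = pd.Series(np.where(half, "h1", "h2"), index=gs.individuals)
        res = gblup.estimate_pairwise_vc(y, pop, grm, "h1", "h2")
        assert res["correlation"] >= 0.8

    def test_requires_thirty_records(self):
        grm, d, ids = toy_grm(40, 60, seed=35)
        pop = pd.Series(["A"] * 10 + ["B"] * 30, index=ids)
        y = pd.Series(np.random.default_rng(0).normal(size=40), index=ids)
        with pytest.raises(ValueError, match="fewer than 30"):
            gblup.estimate_pairwise_vc(y, pop, grm, "A", "B")


class TestBending:
    def test_pd_input_unchanged_elementwise(self):
        M = np.array([[2.0, 0.3], [0.3, 1.0]])
        out = gblup.bend_matrix(M)
        np.testing.assert_array_equal(out, M)

    def test_indefinite_2x2_floors_spectrum(self):
        M = np.array([[1.0, 1.2], [1.2, 1.0]])
        out = gblup.bend_matrix(M, small_positive=1e-4)
        w = np.linalg.eigvalsh(out)
        assert w.min() >= 1e-4 - 1e-10
        assert np.allclose(out, out.T)
        # diagonal moves only by the spectral adjustment
        assert np.abs(np.diag(out) - 1.0).max() < 0.2

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_idempotent_and_pd_on_random_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 4))
        M = 0.5 * (A + A.T)
        b1 = gblup.bend_matrix(M)
        b2 = gblup.bend_matrix(b1)
        assert np.linalg.eigvalsh(b1).min() >= 1e-4 - 1e-10
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_assemble_averages_diagonals_and_bends(self):
        pairwise = {
            ("A", "B"): {"sigma2_a": {"A": 1.0, "B": 2.0}, "sigma_a_cov": 1.6,
                         "sigma2_e": {"A": 3.0, "B": 4.0}},
            ("A", "C"): {"sigma2_a": {"A": 1.2, "C": 1.0}, "sigma_a_cov": 0.5,
                         "sigma2_e": {"A": 3.2, "C": 5.0}},
            ("B", "C"): {"sigma2_a": {"B": 1.8, "C": 1.2}, "sigma_a_cov": 0.4,
                         "sigma2_e": {"B": 4.2, "C": 5.2}},
        }
        vc = gblup.assemble_and_bend(pairwise, ["A", "B", "C"])
        assert np.linalg.eigvalsh(vc.M).min() >= 1e-4 - 1e-10
        assert vc.R[0, 0] == pytest.approx(3.1)
        assert vc.R[0, 1] == 0.0
        with pytest.raises(ValueError, match="missing bivariate"):
            gblup.assemble_and_bend({("A", "B"): pairwise[("A", "B")]},
                                    ["A", "B", "C"])


class TestDerivedParameters:
    @pytest.mark.parametrize("sa2,se2,expect", [
        # printed variance components of the repeatability models whose
        # two-component ratio is internally consistent
        (1.26, 8.95, 0.12), (0.99, 7.49, 0.12),
        (1.62, 11.46, 0.12), (1.55, 11.45, 0.12),
        (0.59, 7.77, 0.07), (0.37, 6.73, 0.05),
        (1.05, 11.53, 0.08), (0.58, 10.96, 0.05),
        (0.49, 5.71, 0.08), (0.0, 5.0, 0.0),
    ])
    def test_heritability_two_component_ratio(self, sa2, se2, expect):
        assert gblup.heritability(sa2, se2) == expect

    def test_heritability_errors(self):
        with pytest.raises(ValueError):
            gblup.heritability(0.0, 0.0)
        with pytest.raises(ValueError):
            gblup.heritability(-1.0, 2.0)

    @pytest.mark.parametrize("m,expect", [
        (np.array([[2.0, 0.0], [0.0, 8.0]]), 0.0),
        (np.array([[2.0, 4.0], [4.0, 8.0]]), 1.0),
        (np.array([[2.0, 2.0], [2.0, 8.0]]), 0.5),
    ])
    def test_genetic_correlation(self, m, expect):
        assert gblup.genetic_correlation(m, 0, 1) == pytest.approx(expect)

    def test_genetic_correlation_zero_variance_errors(self):
        with pytest.raises(ValueError):
            gblup.genetic_correlation(np.array([[0.0, 0.0], [0.0, 1.0]]), 0, 1)
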