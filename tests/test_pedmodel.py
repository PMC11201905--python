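"""Pedigree relationships, repeatability REML/BLUP and corrected phenotypes."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

from multigp import pedmodel
from conftest import kinship_oracle


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


def simulate_records(rel, sa2, spe2, se2, n_par=3, hys_block=20, seed=0,
                     sow_prefix="C"):
    """Repeatability-model records for the sows of a fitted pedigree."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(rel.A + 1e-10 * np.eye(len(rel.order)))
    u = L @ rng.standard_normal(len(rel.order)) * np.sqrt(sa2)
    sows = [i for i in rel.order if i.startswith(sow_prefix)]
    pe = {s: rng.normal(0, np.sqrt(spe2)) for s in sows}
    rows = []
    for par in range(1, n_par + 1):
        for b in range(0, len(sows), hys_block):
            block = sows[b:b + hys_block]
            h = f"p{par}g{b}"
            he = rng.normal(0, np.sqrt(se2))
            for s in block:
                rows.append((s, h, he + u[rel.order[s]] + pe[s]
                             + rng.normal(0, np.sqrt(se2))))
    return pd.DataFrame(rows, columns=["individual", "hys", "value"])


def sired_pedigree(n_sires, n_sows, seed=0):
    rng = np.random.default_rng(seed)
    rows = [("S%d" % i, "0", "0") for i in range(n_sires)]
    rows += [("C%d" % i, "S%d" % rng.integers(n_sires), "0") for i in range(n_sows)]
    return _ped(rows)


class TestAMatrix:
    def test_unrelated_founders_identity(self):
        rel = pedmodel.build_A_matrix(_ped([("a", "0", "0"), ("b", "0", "0")]))
        np.testing.assert_array_equal(rel.A, np.eye(2))

    def test_parent_offspring_textbook_values(self):
        rel = pedmodel.build_A_matrix(_ped([("s", "0", "0"), ("d", "0", "0"),
                                            ("o", "s", "d")]))
        o, s = rel.order["o"], rel.order["s"]
        assert rel.A[o, o] == 1.0
        assert rel.A[o, s] == 0.5

    def test_full_sib_mating_inbreeding_quarter(self):
        """Path counting: offspring of full sibs from unrelated grandparents
        has F = 0.25, so the diagonal is 1.25."""
        rel = pedmodel.build_A_matrix(_ped([
            ("gs", "0", "0"), ("gd", "0", "0"),
            ("f1", "gs", "gd"), ("f2", "gs", "gd"), ("x", "f1", "f2")]))
        assert rel.A[rel.order["x"], rel.order["x"]] == pytest.approx(1.25)

    def test_cycle_detection(self):
        with pytest.raises(ValueError, match="cycle"):
            pedmodel.build_A_matrix(_ped([("a", "b", "0"), ("b", "a", "0")]))

    def test_matches_recursive_kinship_oracle_random_pedigree(self, rng):
        rows = [("F%d" % i, "0", "0") for i in range(10)]
        ids = [r[0] for r in rows]
        for g in range(40):
            s, d = rng.choice(len(ids), 2, replace=False)
            rows.append(("I%d" % g, ids[s], ids[d]))
            ids.append("I%d" % g)
        ped = _ped(rows)
        rel = pedmodel.build_A_matrix(ped)
        A_or, order_or = kinship_oracle(ped)
        perm = [order_or[i] for i in rel.order]
        np.testing.assert_allclose(rel.A, A_or[np.ix_(perm, perm)], atol=1e-12)


class TestBlup:
    def setup_method(self):
        self.rel = pedmodel.build_A_matrix(sired_pedigree(4, 10, seed=1))
        self.records = simulate_records(self.rel, 1.0, 0.5, 2.0, n_par=2,
                                        hys_block=5, seed=2)
        self.spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(
            self.records, self.rel)

    def test_matches_dense_mme_solve(self):
        """Solutions equal a direct normal-equations least-squares solve of the
        full mixed-model system built from explicit incidence matrices."""
        vc = pedmodel.VarianceComponentsSingle(1.0, 0.5, 2.0)
        sol = pedmodel.blup_repeatability(self.spec, self.rel, vc)
        spec = self.spec
        n, p = spec.X.shape
        q_a, q_pe = len(spec.animal_ids), len(spec.pe_ids)
        Z = np.zeros((n, q_a)); Z[np.arange(n), spec.z_idx] = 1
        W = np.zeros((n, q_pe)); W[np.arange(n), spec.w_idx] = 1
        Wall = np.hstack([spec.X, Z, W])
        C = Wall.T @ Wall / vc.sigma2_e
        C[p:p + q_a, p:p + q_a] += np.linalg.inv(self.rel.A) / vc.sigma2_a
        C[p + q_a:, p + q_a:] += np.eye(q_pe) / vc.sigma2_pe
        theta = np.linalg.solve(C, Wall.T @ spec.y / vc.sigma2_e)
        np.testing.assert_allclose(sol.fixed.to_numpy(), theta[:p], atol=1e-8)
        np.testing.assert_allclose(sol.ebv.to_numpy(), theta[p:p + q_a], atol=1e-8)
        np.testing.assert_allclose(sol.pe.to_numpy(), theta[p + q_a:], atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        vc = pedmodel.VarianceComponentsSingle(1e-10, 0.5, 2.0)
        sol = pedmodel.blup_repeatability(self.spec, self.rel, vc)
        assert np.abs(sol.ebv.to_numpy()).max() < 1e-6

    def test_residuals_sum_to_zero_within_estimable_levels(self):
        vc = pedmodel.VarianceComponentsSingle(1.0, 0.5, 2.0)
        sol = pedmodel.blup_repeatability(self.spec, self.rel, vc)
        res = sol.residuals.copy()
        res["hys"] = self.records["hys"].to_numpy()
        # fixed levels beyond the first absorb their residual means except for
        # shrinkage leakage through the random effects; totals stay near zero
        sums = res.groupby("hys")["residual"].sum()
        assert np.abs(sums.to_numpy()).max() < 0.5


class TestReml:
    def test_recovers_truth_on_moderate_data(self):
        rel = pedmodel.build_A_matrix(sired_pedigree(30, 400, seed=3))
        rec = simulate_records(rel, 1.26, 0.8, 8.95, seed=4)
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        vc = pedmodel.reml_repeatability(spec, rel)
        # single replicate at n=400: generous sampling bands
        assert vc.sigma2_e == pytest.approx(8.95, rel=0.2)
        assert vc.sigma2_a + vc.sigma2_pe == pytest.approx(2.06, rel=0.6)

    def test_null_additive_variance_recovered(self):
        rel = pedmodel.build_A_matrix(sired_pedigree(25, 500, seed=5))
        rec = simulate_records(rel, 0.0, 0.8, 8.95, seed=6)
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        vc = pedmodel.reml_repeatability(spec, rel)
        assert vc.h2 <= 0.02

    def test_matches_direct_likelihood_oracle_single_records(self):
        """With one record per sow and no pe term, the repeatability REML must
        agree with a direct optimization of the animal-model restricted
        likelihood evaluated from the covariance form V = ZAZ's_a + Is_e."""
        rel = pedmodel.build_A_matrix(sired_pedigree(40, 400, seed=7))
        rec = simulate_records(rel, 1.5, 0.0, 1.0, n_par=1, hys_block=50, seed=8)
        # two records per sow are required for pe identifiability; to keep the
        # single-record design comparable we estimate with pe fixed near zero
        # by a direct 2-component oracle and compare the fit's likelihood path
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        sows = spec.pe_ids
        Z = np.zeros((len(rec), len(spec.animal_ids)))
        Z[np.arange(len(rec)), spec.z_idx] = 1
        X, y = spec.X, spec.y
        ZAZ = Z @ rel.A @ Z.T

        def m2ll(par):
            sa2, se2 = np.exp(par)
            V = sa2 * ZAZ + se2 * np.eye(len(y))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            b = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ b
            _, ld = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(XtViX)
            return ld + ldx + float(r @ Vi @ r)

        res = scipy.optimize.minimize(m2ll, np.log([1.0, 1.0]), method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        sa2_or, se2_or = np.exp(res.x)

        vc = pedmodel.reml_repeatability(spec, rel, fix_pe_at=1e-8,
                                         tol_param=1e-10)
        assert vc.sigma2_a == pytest.approx(sa2_or, rel=0.02, abs=0.02)
        assert vc.sigma2_e == pytest.approx(se2_or, rel=0.02, abs=0.02)

    def test_invariant_to_contemporary_group_shift(self):
        rel = pedmodel.build_A_matrix(sired_pedigree(30, 400, seed=9))
        rec = simulate_records(rel, 1.5, 0.5, 4.0, seed=10)
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        vc1 = pedmodel.reml_repeatability(spec, rel)
        shifted = rec.copy()
        first = shifted["hys"].iloc[0]
        shifted.loc[shifted["hys"] == first, "value"] += 100.0
        spec2 = pedmodel.RepeatabilityModelSpec.from_phenotypes(shifted, rel)
        vc2 = pedmodel.reml_repeatability(spec2, rel)
        assert vc1.sigma2_a == pytest.approx(vc2.sigma2_a, rel=1e-3, abs=1e-5)
        assert vc1.sigma2_e == pytest.approx(vc2.sigma2_e, rel=1e-3, abs=1e-5)

    def test_requires_repeated_records(self):
        rel = pedmodel.build_A_matrix(sired_pedigree(3, 10, seed=11))
        rec = simulate_records(rel, 1.0, 0.5, 2.0, n_par=1, hys_block=5, seed=12)
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        with pytest.raises(ValueError, match="identifiable"):
            pedmodel.reml_repeatability(spec, rel)


class TestCorrectedPhenotypes:
    def _blup(self):
        rel = pedmodel.build_A_matrix(sired_pedigree(4, 12, seed=13))
        rec = simulate_records(rel, 1.0, 0.5, 2.0, n_par=2, hys_block=6, seed=14)
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        return pedmodel.blup_repeatability(
            spec, rel, pedmodel.VarianceComponentsSingle(1.0, 0.5, 2.0))

    def test_yc_equals_ebv_plus_mean_residual(self):
        blup = self._blup()
        yc = pedmodel.corrected_phenotypes(blup).values
        by_sow = blup.residuals.groupby("individual")["residual"].mean()
        for _, row in yc.iterrows():
            assert row["y_c"] == pytest.approx(
                blup.ebv[row["individual"]] + by_sow[row["individual"]], abs=1e-12)

    def test_mean_zero_residuals_leave_ebv(self):
        blup = self._blup()
        sow = blup.residuals["individual"].iloc[0]
        blup.residuals.loc[blup.residuals["individual"] == sow, "residual"] = [1.0, -1.0]
        yc = pedmodel.corrected_phenotypes(blup).values.set_index("individual")
        assert yc.loc[sow, "y_c"] == pytest.approx(blup.ebv[sow])

    def test_three_record_toy_matches_hand_mme(self):
        """2 sows, one hys level, hand-solved mixed-model equations."""
        ped = _ped([("C1", "0", "0"), ("C2", "0", "0")])
        rel = pedmodel.build_A_matrix(ped)
        rec = pd.DataFrame({
            "individual": ["C1", "C1", "C2"],
            "hys": ["h1", "h1", "h1"],
            "value": [10.0, 12.0, 8.0],
        })
        spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
        vc = pedmodel.VarianceComponentsSingle(2.0, 1.0, 4.0)
        sol = pedmodel.blup_repeatability(spec, rel, vc)
        X = np.array([[1.0], [1.0], [1.0]])
        Z = np.array([[1.0, 0], [1, 0], [0, 1]])
        Wall = np.hstack([X, Z, Z])
        C = Wall.T @ Wall / 4.0
        C[1:3, 1:3] += np.eye(2) / 2.0
        C[3:, 3:] += np.eye(2) / 1.0
        theta = np.linalg.solve(C, Wall.T @ rec["value"].to_numpy() / 4.0)
        resid = rec["value"].to_numpy() - Wall @ theta
        yc_hand = {
            "C1": theta[1] + resid[:2].mean(),
            "C2": theta[2] + resid[2],
        }
        yc = pedmodel.corrected_phenotypes(sol).values.set_index("individual")
        for s, v in yc_hand.items():
            assert yc.loc[s, "y_c"] == pytest.approx(v, abs=1e-10)

    def test_correlation_with_true_bv_increases_in_h2(self):
        cors = []
        for h2_idx, (sa2, se2) in enumerate([(0.5, 9.5), (2.0, 8.0), (5.0, 5.0)]):
            rel = pedmodel.build_A_matrix(sired_pedigree(20, 300, seed=20))
            rng = np.random.default_rng(21)
            L = np.linalg.cholesky(rel.A + 1e-10 * np.eye(len(rel.order)))
            u = L @ rng.standard_normal(len(rel.order)) * np.sqrt(sa2)
            sows = [i for i in rel.order if i.startswith("C")]
            rows = []
            for par in (1, 2, 3):
                for b in range(0, len(sows), 20):
                    he = rng.normal(0, np.sqrt(se2))
                    for s in sows[b:b + 20]:
                        rows.append((s, f"p{par}g{b}",
                                     he + u[rel.order[s]] + rng.normal(0, np.sqrt(se2))))
            rec = pd.DataFrame(rows, columns=["individual", "hys", "value"])
            spec = pedmodel.RepeatabilityModelSpec.from_phenotypes(rec, rel)
            vc = pedmodel.VarianceComponentsSingle(sa2, 1e-6, se2)
            blup = pedmodel.blup_repeatability(spec, rel, vc)
            yc = pedmodel.corrected_phenotypes(blup).values.set_index("individual")
            truth = np.array([u[rel.order[s]] for s in yc.index])
            cors.append(np.corrcoef(yc["y_c"], truth)[0, 1])
        assert cors[0] < cors[1] < cors[2]
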