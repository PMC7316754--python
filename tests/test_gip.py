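"""GIP decomposition: eigen conventions, CIs, scores, and the two GWAS routes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gipkit import assoc, gip, ldsc, simdata
from gipkit.gip import (
    GipDecomposition,
    gip_decompose,
    gip_gwas_individual,
    gip_gwas_summary,
    gip_h2,
    gip_scores,
    monte_carlo_loading_ci,
    predict_gip_pheno_corr,
    sample_pheno_corr,
)


def _random_psd(rng, t, scale=0.05):
    a = rng.normal(size=(t, t))
    return scale * (a @ a.T) / t


class TestDecomposition:
    def test_scalar_matrix_returns_identity_loadings(self):
        res = gip_decompose(0.03 * np.eye(3))
        assert np.allclose(res.loadings, np.eye(3), atol=1e-12)
        assert np.allclose(res.eigenvalues, 0.03)

    def test_two_by_two_hand_example(self):
        c = np.array([[0.04, 0.03], [0.03, 0.04]])
        res = gip_decompose(c, allow_two_traits=True)
        assert res.eigenvalues == pytest.approx([0.07, 0.01], abs=1e-12)
        s = 0.7071068
        assert res.loadings[:, 0] == pytest.approx([s, s], abs=1e-6)
        assert res.loadings[:, 1] == pytest.approx([s, -s], abs=1e-6)

    def test_exchangeable_four_trait_case(self):
        c = 0.03 * (0.3 * np.eye(4) + 0.7 * np.ones((4, 4)))
        res = gip_decompose(c)
        assert res.eigenvalues[0] == pytest.approx(0.03 * (1 + 3 * 0.7), abs=1e-12)
        assert res.loadings[:, 0] == pytest.approx([0.5, 0.5, 0.5, 0.5], abs=1e-10)
        assert res.explained_total[0] == pytest.approx((1 + 3 * 0.7) / 4, abs=1e-12)

    def test_two_traits_require_override(self):
        with pytest.raises(ValueError):
            gip_decompose(np.eye(2))

    def test_asymmetric_input_rejected(self):
        c = np.array([[0.1, 0.2, 0.0], [0.0, 0.1, 0.0], [0.0, 0.0, 0.1]])
        with pytest.raises(ValueError, match="asymmetric"):
            gip_decompose(c)

    def test_negative_eigenvalues_flagged_not_clipped(self):
        c = np.array([[0.02, 0.05, 0.0], [0.05, 0.02, 0.0], [0.0, 0.0, 0.01]])
        res = gip_decompose(c)
        assert res.eigenvalues.min() < 0
        assert any("negative eigenvalue" in f for f in res.flags)

    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_reconstruction_and_variance_identities(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(3, 7))
        c = _random_psd(rng, t) + 1e-4 * np.eye(t)
        res = gip_decompose(c)
        a, lam = res.loadings, res.eigenvalues
        assert np.max(np.abs(a @ np.diag(lam) @ a.T - res.C_G)) < 1e-10
        assert np.max(np.abs(a.T @ a - np.eye(t))) < 1e-10
        assert res.explained_total.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(res.explained_per_trait.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.diff(lam) <= 1e-12)
        # sign convention: column sums positive (or largest entry positive)
        sums = a.sum(axis=0)
        for k in range(t):
            if abs(sums[k]) > 1e-9:
                assert sums[k] > 0

    def test_no_signal_errors(self):
        res = gip_decompose(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="signal"):
            _ = res.explained_total


class TestMonteCarloCi:
    def _point(self):
        c = np.array(
            [[0.06, 0.02, 0.01], [0.02, 0.04, 0.015], [0.01, 0.015, 0.03]]
        )
        return gip_decompose(c)

    def test_zero_covariance_gives_zero_width(self):
        res = self._point()
        ci = monte_carlo_loading_ci(res, np.zeros((6, 6)), n_draws=200, seed=0)
        assert np.allclose(ci[..., 0], res.loadings, atol=1e-12)
        assert np.allclose(ci[..., 1], res.loadings, atol=1e-12)

    def test_width_scales_with_sqrt_of_covariance(self):
        res = self._point()
        j = 1e-6 * np.eye(6)
        ci1 = monte_carlo_loading_ci(res, j, n_draws=4000, seed=1)
        ci2 = monte_carlo_loading_ci(res, j / 4.0, n_draws=4000, seed=1)
        w1 = (ci1[..., 1] - ci1[..., 0]).mean()
        w2 = (ci2[..., 1] - ci2[..., 0]).mean()
        assert w2 / w1 == pytest.approx(0.5, abs=0.05)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_loading_ci(self._point(), np.zeros((6, 6)), n_draws=50)

    def test_non_conformable_covariance_rejected(self):
        with pytest.raises(ValueError, match="conformable"):
            monte_carlo_loading_ci(self._point(), np.zeros((5, 5)), n_draws=200)

    def test_point_estimate_inside_intervals(self):
        res = self._point()
        j = 1e-5 * np.eye(6)
        ci = monte_carlo_loading_ci(res, j, n_draws=500, seed=2)
        assert np.all(ci[..., 0] <= res.loadings + 1e-6)
        assert np.all(ci[..., 1] >= res.loadings - 1e-6)


class TestScores:
    def _traits(self, rng, n=300, t=3):
        y = rng.normal(size=(n, t))
        return pd.DataFrame(y, columns=[f"trait{i+1}" for i in range(t)])

    def test_identity_loadings_reproduce_standardized_traits(self):
        rng = np.random.default_rng(3)
        traits = self._traits(rng)
        res = gip_decompose(0.02 * np.eye(3))
        s = gip_scores(traits, res)
        expect = np.column_stack([assoc.standardize(traits[c]) for c in traits])
        assert np.allclose(s.to_numpy(), expect, atol=1e-12)

    def test_score_covariance_identity(self):
        rng = np.random.default_rng(4)
        traits = self._traits(rng)
        c = np.array([[0.05, 0.02, 0.01], [0.02, 0.04, 0.02], [0.01, 0.02, 0.03]])
        res = gip_decompose(c)
        s = gip_scores(traits, res).to_numpy()
        c_p = sample_pheno_corr(traits)
        expect = res.loadings.T @ c_p @ res.loadings
        assert np.allclose(np.cov(s, rowvar=False), expect, atol=1e-10)

    def test_trait_name_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        traits = self._traits(rng).rename(columns={"trait1": "oops"})
        res = gip_decompose(0.02 * np.eye(3))
        with pytest.raises(ValueError, match="do not match"):
            gip_scores(traits, res)


class TestPredictedCorrelations:
    def test_identity_pheno_corr_gives_orthogonal_gips(self):
        c = np.array([[0.05, 0.02, 0.01], [0.02, 0.04, 0.02], [0.01, 0.02, 0.03]])
        res = gip_decompose(c)
        pc = predict_gip_pheno_corr(res, np.eye(3))
        off = pc.gip_corr[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_exchangeable_case_decorrelates_gip1_gip2(self):
        c_g = 0.03 * (0.3 * np.eye(4) + 0.7 * np.ones((4, 4)))
        c_p = 0.77 * np.eye(4) + 0.23 * np.ones((4, 4))
        res = gip_decompose(c_g)
        pc = predict_gip_pheno_corr(res, c_p)
        assert pc.gip_corr[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_empirical_scores(self):
        rng = np.random.default_rng(6)
        traits = pd.DataFrame(
            rng.multivariate_normal(np.zeros(3), 0.5 * np.eye(3) + 0.5, size=400),
            columns=["trait1", "trait2", "trait3"],
        )
        res = gip_decompose(_random_psd(rng, 3) + 0.01 * np.eye(3))
        c_p = sample_pheno_corr(traits)
        pred = predict_gip_pheno_corr(res, c_p)
        emp = np.corrcoef(gip_scores(traits, res).to_numpy(), rowvar=False)
        assert np.allclose(pred.gip_corr, emp, atol=1e-10)


class TestGipH2:
    def test_exchangeable_closed_form(self):
        c_g = 0.03 * (0.3 * np.eye(4) + 0.7 * np.ones((4, 4)))
        c_p = 0.77 * np.eye(4) + 0.23 * np.ones((4, 4))
        res = gip_decompose(c_g)
        h2 = gip_h2(res, c_p)
        assert h2[0] == pytest.approx(0.093 / 1.69, abs=1e-10)

    def test_identity_case_returns_diagonal(self):
        c = np.diag([0.05, 0.04, 0.03])
        res = gip_decompose(c)
        assert gip_h2(res, np.eye(3)) == pytest.approx([0.05, 0.04, 0.03], abs=1e-12)


class TestGwasRoutes:
    def test_identity_model_reproduces_trait_gwas(self, small_sim):
        res = gip.GipResults(
            loadings=np.eye(4),
            eigenvalues=np.ones(4),
            C_G=np.eye(4),
            trait_names=small_sim.est.trait_names,
        )
        out = gip_gwas_individual(small_sim.cohort, res, ["age", "sex"])
        for k, name in enumerate(small_sim.est.trait_names):
            ref = small_sim.trait_tables[k]
            assert np.allclose(out[k]["BETA"], ref["BETA"], atol=1e-12)
            assert np.allclose(out[k]["SE"], ref["SE"], atol=1e-12)

    def test_summary_route_closed_form_se(self):
        s, rho = 0.04, 0.3
        h = np.sqrt(0.5)
        res = gip.GipResults(
            loadings=np.array([[h, h], [h, -h]]),
            eigenvalues=np.array([0.07, 0.01]),
            C_G=np.array([[0.04, 0.03], [0.03, 0.04]]),
            trait_names=("trait1", "trait2"),
        )
        tab = pd.DataFrame(
            {
                "SNP": ["s1"], "CHR": [1], "POS": [100], "EA": ["A"], "OA": ["G"],
                "EAF": [0.2], "BETA": [0.1], "SE": [s], "P": [0.5], "N": [1000],
            }
        )
        c_p = np.array([[1.0, rho], [rho, 1.0]])
        out = gip_gwas_summary([tab, tab.copy()], res, c_p)
        assert out[0].loc[0, "SE"] == pytest.approx(s * np.sqrt(1 + rho), abs=1e-10)
        assert out[1].loc[0, "SE"] == pytest.approx(s * np.sqrt(1 - rho), abs=1e-10)

    def test_routes_agree_on_simulation(self, small_sim):
        res = small_sim.gip
        ind = gip_gwas_individual(small_sim.cohort, res, ["age", "sex"])
        summ = gip_gwas_summary(small_sim.trait_tables, res, small_sim.pheno_corr)
        for k in range(4):
            z1 = (ind[k]["BETA"] / ind[k]["SE"]).to_numpy()
            z2 = (summ[k]["BETA"] / summ[k]["SE"]).to_numpy()
            assert np.corrcoef(z1, z2)[0, 1] > 0.999
            assert np.median(np.abs(z1 - z2)) < 0.05

    def test_gips_are_genetically_independent(self, small_sim):
        """The defining property: pairwise genetic covariance of GIP scans
        is statistically indistinguishable from zero."""
        ind = gip_gwas_individual(small_sim.cohort, small_sim.gip, ["age", "sex"])
        for i in range(4):
            for j in range(i + 1, 4):
                fit = ldsc.ldsc_bivariate(
                    ind[i], ind[j], small_sim.ld_scores,
                    m=small_sim.spec.m, n_blocks=60,
                )
                assert abs(fit.est) < 2 * fit.est_se

    def test_loading_transfer_to_fresh_cohort(self, small_sim):
        """Discovery loadings applied to a new cohort from the same
        architecture give a GIP1 h2 compatible with the discovery estimate."""
        res = small_sim.gip
        cohort2 = simdata.make_genotypes(3000, small_sim.spec, seed=55)
        cohort2 = simdata.simulate_traits(cohort2, small_sim.arch, seed=56)
        ind1 = gip_gwas_individual(small_sim.cohort, res, ["age", "sex"])[0]
        ind2 = gip_gwas_individual(cohort2, res, ["age", "sex"])[0]
        l2 = ldsc.ld_scores_empirical(cohort2.dosages, cohort2.variant_meta)
        fit1 = ldsc.ldsc_univariate(ind1, small_sim.ld_scores, m=small_sim.spec.m, n_blocks=60)
        fit2 = ldsc.ldsc_univariate(ind2, l2, m=small_sim.spec.m, n_blocks=60)
        se = np.hypot(fit1.est_se, fit2.est_se)
        assert abs(fit1.est - fit2.est) < 2 * se
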