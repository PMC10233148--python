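"""GREML variance components, BLUP predictions and their dense oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space

from nirblup import (
    FitOptions,
    SimulationConfig,
    build_grm,
    fit_bivariate,
    fit_single_trait,
    grm_condition,
    predict_gebv,
    reml_loglik,
    simulate_genotypes,
    simulate_phenotypes,
)
from nirblup.grm import GRM

from conftest import random_grm, random_psd


def contrast_oracle(y, X, V):
    """Restricted loglik via orthonormal error contrasts (independent route).

    Equals -1/2 [log|V| + log|X'V^-1 X| + y'Py] through the identity
    |A'VA| = |V| |X'V^-1 X| / |X'X| for A an orthonormal basis of null(X').
    """
    A = null_space(X.T)
    M = A.T @ V @ A
    sign, ld = np.linalg.slogdet(M)
    assert sign > 0
    quad = y @ A @ np.linalg.solve(M, A.T @ y)
    _, ldx = np.linalg.slogdet(X.T @ X)
    return -0.5 * (ld + ldx + quad)


def toy_bivariate_instance(rng, n_lines, n_ep, n_nir):
    """Random small instance with per-trait missingness."""
    G = random_grm(rng, n_lines)
    ids = [f"L{i:02d}" for i in range(n_lines)]
    grm = GRM(ids, G)
    ep_lines = sorted(rng.choice(n_lines, size=n_ep, replace=False))
    nir_lines = sorted(rng.choice(n_lines, size=n_nir, replace=False))
    y_ep = pd.Series(rng.standard_normal(n_ep), index=[ids[i] for i in ep_lines])
    y_nir = pd.Series(rng.standard_normal(n_nir), index=[ids[i] for i in nir_lines])
    return grm, y_ep, y_nir, ep_lines, nir_lines


def assemble_dense_V(G, ep_lines, nir_lines, G0, R0):
    """Direct dense covariance of the stacked (EP, NIR) record vector."""
    n1, n2 = len(ep_lines), len(nir_lines)
    V = np.zeros((n1 + n2, n1 + n2))
    V[:n1, :n1] = G0[0, 0] * G[np.ix_(ep_lines, ep_lines)] + R0[0, 0] * np.eye(n1)
    V[n1:, n1:] = G0[1, 1] * G[np.ix_(nir_lines, nir_lines)] + R0[1, 1] * np.eye(n2)
    V[:n1, n1:] = G0[0, 1] * G[np.ix_(ep_lines, nir_lines)]
    for a, la in enumerate(ep_lines):
        for b, lb in enumerate(nir_lines):
            if la == lb:
                V[a, n1 + b] += R0[0, 1]
    V[n1:, :n1] = V[:n1, n1:].T
    return V


class TestRemlLoglik:
    def test_single_trait_matches_contrast_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(5, 21))
            G = random_grm(rng, n)
            ids = [f"L{i:02d}" for i in range(n)]
            y = rng.standard_normal(n)
            sg, se = rng.uniform(0.2, 2.0, size=2)
            got = reml_loglik(y, ids, np.zeros(n, int), GRM(ids, G), [[sg]], [[se]])
            want = contrast_oracle(y, np.ones((n, 1)), sg * G + se * np.eye(n))
            assert got == pytest.approx(want, abs=1e-10)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        n, c = 12, 3.0
        G = random_grm(rng, n)
        ids = [f"L{i}" for i in range(n)]
        y = rng.standard_normal(n)
        grm = GRM(ids, G)
        ll1 = reml_loglik(y, ids, np.zeros(n, int), grm, [[0.7]], [[0.4]])
        ll2 = reml_loglik(c * y, ids, np.zeros(n, int), grm, [[c**2 * 0.7]], [[c**2 * 0.4]])
        assert ll2 - ll1 == pytest.approx(-(n - 1) * np.log(c), abs=1e-9)

    def test_identity_grm_depends_on_variance_sum_only(self):
        rng = np.random.default_rng(2)
        n = 10
        ids = [f"L{i}" for i in range(n)]
        grm = GRM(ids, np.eye(n))
        y = rng.standard_normal(n)
        ll = lambda sg, se: reml_loglik(y, ids, np.zeros(n, int), grm, [[sg]], [[se]])
        assert ll(0.3, 0.7) == pytest.approx(ll(0.9, 0.1), abs=1e-10)
        assert ll(0.3, 0.7) != pytest.approx(ll(0.3, 0.9), abs=1e-6)


class TestSingleTraitFit:
    def test_fitted_point_is_a_stationary_maximum(self, small_blues, small_grm):
        ep, _ = small_blues
        fit = fit_single_trait(ep, small_grm)
        ids = list(ep.index)
        base = reml_loglik(
            ep.to_numpy(), ids, np.zeros(len(ep), int), small_grm,
            [[fit.sigma2_g]], [[fit.sigma2_e]],
        )
        for dg in (-0.05, 0.05):
            for de in (-0.05, 0.05):
                ll = reml_loglik(
                    ep.to_numpy(), ids, np.zeros(len(ep), int), small_grm,
                    [[fit.sigma2_g * (1 + dg)]], [[fit.sigma2_e * (1 + de)]],
                )
                assert ll < base + 1e-9

    def test_invariant_to_line_reordering(self, small_blues, small_grm):
        ep, _ = small_blues
        f1 = fit_single_trait(ep, small_grm)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(ep))
        f2 = fit_single_trait(ep.iloc[perm], small_grm)
        assert f1.sigma2_g == pytest.approx(f2.sigma2_g, rel=1e-8)
        pd.testing.assert_series_equal(f1.gebv, f2.gebv, rtol=1e-8)

    def test_shrinks_everything_to_zero_without_genetic_signal(self):
        rng = np.random.default_rng(4)
        n = 80
        ids = [f"L{i:02d}" for i in range(n)]
        grm = GRM(ids, random_grm(rng, n))
        y = pd.Series(rng.standard_normal(n), index=ids)
        # pure noise: sigma_g collapses toward the floor and GEBVs toward 0
        fit = fit_single_trait(y, grm)
        assert fit.sigma2_g < 0.3 * fit.sigma2_e
        assert fit.gebv.abs().max() < y.std()


class TestBivariateFit:
    def test_loglik_matches_dense_oracle_with_missingness(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(6, 20))
            grm, y_ep, y_nir, ep_l, nir_l = toy_bivariate_instance(
                rng, n, int(rng.integers(3, n)), int(rng.integers(3, n))
            )
            G0 = random_psd(rng, 2)
            R0 = random_psd(rng, 2)
            y = np.concatenate([y_ep.to_numpy(), y_nir.to_numpy()])
            lines = list(y_ep.index) + list(y_nir.index)
            traits = np.r_[np.zeros(len(y_ep), int), np.ones(len(y_nir), int)]
            got = reml_loglik(y, lines, traits, grm, G0, R0)
            V = assemble_dense_V(grm.values, ep_l, nir_l, G0, R0)
            X = np.zeros((len(y), 2))
            X[: len(y_ep), 0] = 1
            X[len(y_ep) :, 1] = 1
            assert got == pytest.approx(contrast_oracle(y, X, V), abs=1e-10)

    def test_free_fit_dominates_constrained_fit(self, small_blues, small_grm):
        ep, nir = small_blues
        free = fit_bivariate(ep, nir, small_grm)
        constrained = fit_bivariate(
            ep, nir, small_grm, FitOptions(fix_genetic_cov=True)
        )
        assert free.loglik >= constrained.loglik - 1e-6

    def test_reduces_to_single_trait_when_second_trait_absent(self, small_blues, small_grm):
        ep, _ = small_blues
        single = fit_single_trait(ep, small_grm)
        empty = pd.Series(dtype=float)
        with pytest.warns(UserWarning):
            biv = fit_bivariate(ep, empty, small_grm)
        assert biv.G0[0, 0] == pytest.approx(single.sigma2_g, rel=1e-6)
        assert biv.R0[0, 0] == pytest.approx(single.sigma2_e, rel=1e-6)
        np.testing.assert_allclose(
            biv.gebv_ep.to_numpy(), single.gebv.to_numpy(), atol=1e-8
        )

    def test_frozen_covariances_reproduce_independent_single_fits(self, small_grm):
        # with both covariances held at zero the bivariate likelihood
        # factorizes, so the joint fit must equal the two marginal fits
        rng = np.random.default_rng(6)
        ids = small_grm.line_ids
        y1 = pd.Series(rng.standard_normal(len(ids)), index=ids)
        y2 = pd.Series(rng.standard_normal(len(ids)), index=ids)
        opts = FitOptions(fix_genetic_cov=True)
        # also freeze the residual covariance by splitting the traits over
        # disjoint line sets (no line observed for both)
        half = len(ids) // 2
        y1h, y2h = y1.iloc[:half], y2.iloc[half:]
        with pytest.warns(UserWarning):
            biv = fit_bivariate(y1h, y2h, small_grm, opts)
        s1 = fit_single_trait(y1h, small_grm)
        s2 = fit_single_trait(y2h, small_grm)
        assert biv.G0[0, 0] == pytest.approx(s1.sigma2_g, rel=1e-4, abs=1e-8)
        assert biv.G0[1, 1] == pytest.approx(s2.sigma2_g, rel=1e-4, abs=1e-8)

    def test_near_separability_with_uncorrelated_traits(self):
        # data generated with r_g = r_e = 0: the free bivariate fit agrees
        # with the single-trait fits up to the O(1/sqrt(n)) sampling coupling
        cfg = SimulationConfig(
            n_lines=300, n_markers=600, h2_ep=0.5, h2_nir=0.5, r_g=0.0, r_e=0.0,
            seed=7, reps_per_line=1,
        )
        geno = simulate_genotypes(cfg)
        _, truth = simulate_phenotypes(geno, cfg)
        rng = np.random.default_rng(8)
        y1 = pd.Series(
            truth.true_bv_ep.to_numpy() + rng.normal(0, np.sqrt(0.5), 300),
            index=truth.true_bv_ep.index,
        )
        y2 = pd.Series(
            truth.true_bv_nir.to_numpy() + rng.normal(0, np.sqrt(0.5), 300),
            index=truth.true_bv_nir.index,
        )
        grm = grm_condition(build_grm(geno))
        biv = fit_bivariate(y1, y2, grm)
        s1 = fit_single_trait(y1, grm)
        assert abs(biv.r_g) < 0.35
        assert biv.G0[0, 0] == pytest.approx(s1.sigma2_g, abs=0.08)
        # GEBVs differ only through the sampling noise of the estimated
        # cross-trait covariance; they stay tightly aligned
        assert np.corrcoef(biv.gebv_ep, s1.gebv)[0, 1] > 0.9

    def test_r_g_definition_consistency(self, small_blues, small_grm):
        ep, nir = small_blues
        fit = fit_bivariate(ep, nir, small_grm)
        assert fit.r_g == pytest.approx(
            fit.G0[0, 1] / np.sqrt(fit.G0[0, 0] * fit.G0[1, 1]), abs=1e-12
        )
        assert abs(fit.r_g) <= 1.0


class TestPredictGebv:
    def test_duplicate_line_gets_identical_prediction(self):
        rng = np.random.default_rng(9)
        n = 25
        G = random_grm(rng, n)
        # line n-1 is a genetic copy of line 0
        G[n - 1, :] = G[0, :]
        G[:, n - 1] = G[:, 0]
        G[n - 1, n - 1] = G[0, 0]
        ids = [f"L{i:02d}" for i in range(n)]
        grm = GRM(ids, G)
        y = pd.Series(rng.standard_normal(n - 5), index=ids[: n - 5])
        fit = fit_single_trait(y, grm)
        # neither copy is phenotyped? L00 is; predictions must still agree
        assert fit.gebv[ids[0]] == pytest.approx(fit.gebv[ids[-1]], abs=1e-8)

    def test_held_out_lines_match_dense_conditional_mean(self):
        rng = np.random.default_rng(10)
        n = 15
        G = random_grm(rng, n)
        ids = [f"L{i:02d}" for i in range(n)]
        grm = GRM(ids, G)
        obs = list(range(10))
        y = pd.Series(rng.standard_normal(10), index=[ids[i] for i in obs])
        fit = fit_single_trait(y, grm)
        sg, se = fit.sigma2_g, fit.sigma2_e
        V = sg * G[np.ix_(obs, obs)] + se * np.eye(10)
        X = np.ones((10, 1))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy())
        resid = y.to_numpy() - X @ b
        oracle = sg * G[:, obs] @ Vi @ resid
        np.testing.assert_allclose(fit.gebv.to_numpy(), oracle, atol=1e-8)

    def test_unknown_line_is_reported(self, small_blues, small_grm):
        ep, _ = small_blues
        fit = fit_single_trait(ep, small_grm)
        from nirblup import DataError

        with pytest.raises(DataError, match="NOPE"):
            predict_gebv(fit, ["NOPE"])

    def test_subsetting_returns_requested_lines(self, small_blues, small_grm):
        ep, nir = small_blues
        fit = fit_bivariate(ep, nir, small_grm)
        out = predict_gebv(fit, small_grm.line_ids[:5])
        assert list(out["line_id"]) == small_grm.line_ids[:5]
        assert {"gebv_ep", "gebv_nir"} <= set(out.columns)
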