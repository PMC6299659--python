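"""Gibbs samplers: BRR vs ridge oracle, BLASSO shrinkage/selection, RKHS kernel."""

import numpy as np
import pandas as pd
import pytest

from sprucegs._errors import ModelError
from sprucegs.marker_models import (
    McmcSettings,
    PriorSpec,
    convergence_check,
    fit_blasso,
    fit_brr,
    fit_rkhs,
    gaussian_kernel,
    gebv_from_effects,
    geweke_z,
)
from sprucegs.relationship import RelationshipMatrix
from sprucegs.simdata import GenotypeMatrix


def _sim_markers(rng, n, m, n_causal, h2):
    dos = rng.integers(0, 3, size=(n, m)).astype(float)
    geno = GenotypeMatrix(
        [f"s{i}" for i in range(n)], [f"m{j}" for j in range(m)], dos
    )
    beta = np.zeros(m)
    causal = rng.choice(m, n_causal, replace=False)
    beta[causal] = rng.standard_normal(n_causal)
    g = (dos - 1.0) @ beta
    g = (g - g.mean()) / g.std()
    e = rng.standard_normal(n) * np.sqrt((1 - h2) / h2)
    y = g + e
    y = (y - y.mean()) / y.std()
    return geno, beta, causal, y


class TestMcmcSettings:
    def test_retained_count(self):
        s = McmcSettings(15_000, 5_000, 10)
        assert s.n_retained == 1000
        assert McmcSettings.paper().n_retained == 100

    def test_invalid_settings_rejected(self):
        with pytest.raises(ModelError):
            McmcSettings(100, 200, 10)
        with pytest.raises(ModelError):
            McmcSettings(100, 50, 0)


class TestBRR:
    def test_matches_closed_form_ridge_with_fixed_variances(self):
        rng = np.random.default_rng(0)
        geno, beta, _, y = _sim_markers(rng, 150, 40, 40, 0.6)
        sm2, se2 = 0.01, 0.5
        eff = fit_brr(
            y, geno, mcmc=McmcSettings(8000, 2000, 2, seed=3),
            fix_sigma_m=sm2, fix_sigma_e=se2,
        )
        # exact posterior mean with fixed variances: the joint (intercept,
        # effects) normal system [[n, 1'Z], [Z'1, Z'Z + λI]]
        Z = geno.dosages - 1.0
        n, m = Z.shape
        lam = se2 / sm2
        C = np.block(
            [[np.array([[float(n)]]), Z.sum(axis=0)[None, :]],
             [Z.sum(axis=0)[:, None], Z.T @ Z + lam * np.eye(m)]]
        )
        sol = np.linalg.solve(C, np.concatenate([[y.sum()], Z.T @ y]))
        ridge = sol[1:]
        # Monte Carlo error via batch means (Gibbs samples autocorrelate)
        k = eff.effect_samples.shape[0]
        batches = np.array_split(eff.effect_samples, 20, axis=0)
        bm = np.array([b.mean(axis=0) for b in batches])
        mc_se = bm.std(axis=0, ddof=1) / np.sqrt(len(batches))
        assert np.mean(np.abs(eff.effects - ridge) < 4 * mc_se + 1e-3) > 0.9
        np.testing.assert_allclose(eff.effects, ridge, atol=0.02)

    def test_null_phenotype_shrinks_to_zero(self):
        rng = np.random.default_rng(1)
        geno, _, _, _ = _sim_markers(rng, 100, 30, 5, 0.5)
        y = np.zeros(100)
        eff = fit_brr(y + rng.normal(0, 1e-12, 100), geno,
                      mcmc=McmcSettings(4000, 1000, 2, seed=1))
        assert np.abs(eff.effects).max() < 1e-3

    def test_recovers_large_effect_architecture(self):
        rng = np.random.default_rng(2)
        geno, beta, causal, y = _sim_markers(rng, 800, 500, 10, 0.5)
        eff = fit_brr(y, geno, mcmc=McmcSettings.desk(seed=2))
        r = np.corrcoef(eff.effects, beta)[0, 1]
        assert r > 0.4

    def test_bit_reproducible(self):
        rng = np.random.default_rng(3)
        geno, _, _, y = _sim_markers(rng, 80, 30, 10, 0.5)
        e1 = fit_brr(y, geno, mcmc=McmcSettings(2000, 500, 5, seed=7))
        e2 = fit_brr(y, geno, mcmc=McmcSettings(2000, 500, 5, seed=7))
        assert np.array_equal(e1.effect_samples, e2.effect_samples)

    def test_retained_sample_count_as_configured(self):
        rng = np.random.default_rng(4)
        geno, _, _, y = _sim_markers(rng, 50, 20, 5, 0.5)
        eff = fit_brr(y, geno, mcmc=McmcSettings(2001, 500, 7, seed=1))
        assert eff.n_retained == (2001 - 500) // 7


class TestBLASSO:
    def test_huge_fixed_lambda_total_shrinkage(self):
        rng = np.random.default_rng(5)
        geno, _, _, y = _sim_markers(rng, 100, 30, 10, 0.5)
        eff = fit_blasso(
            y, geno, mcmc=McmcSettings(4000, 1000, 2, seed=1), fix_lambda2=1e6
        )
        assert np.abs(eff.effects).max() < 1e-2

    def test_selects_sparse_causal_markers(self):
        rng = np.random.default_rng(6)
        geno, beta, causal, y = _sim_markers(rng, 500, 1000, 5, 0.6)
        eff = fit_blasso(y, geno, mcmc=McmcSettings(6000, 2000, 4, seed=2))
        null = np.setdiff1d(np.arange(1000), causal)
        med_causal = np.median(np.abs(eff.effects[causal]))
        med_null = np.median(np.abs(eff.effects[null]))
        assert med_causal > 5 * med_null

    def test_agrees_with_brr_on_dense_architecture(self):
        rng = np.random.default_rng(7)
        geno, beta, _, y = _sim_markers(rng, 400, 300, 300, 0.5)
        mc = McmcSettings(6000, 2000, 4, seed=3)
        gb = gebv_from_effects(fit_brr(y, geno, mcmc=mc), geno)
        gl = gebv_from_effects(fit_blasso(y, geno, mcmc=mc), geno)
        assert np.corrcoef(gb, gl)[0, 1] > 0.95


class TestGaussianKernel:
    def test_identical_rows_give_one(self):
        dos = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        geno = GenotypeMatrix(list("abc"), ["m1", "m2", "m3"], dos)
        K = gaussian_kernel(geno, h=0.25, scale_distance=False)
        assert K.values[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(K.values) == 1.0)

    def test_unscaled_distance_hand_example(self):
        dos = np.array([[0.0], [2.0]])
        geno = GenotypeMatrix(["a", "b"], ["m1"], dos)
        K = gaussian_kernel(geno, h=0.25, scale_distance=False)
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_vanishing_bandwidth_gives_rank_one(self):
        rng = np.random.default_rng(8)
        dos = rng.integers(0, 3, size=(6, 40)).astype(float)
        geno = GenotypeMatrix([f"s{i}" for i in range(6)],
                              [f"m{j}" for j in range(40)], dos)
        K = gaussian_kernel(geno, h=1e-9)
        assert np.all(K.values > 0.999)

    def test_nonpositive_bandwidth_fatal(self):
        geno = GenotypeMatrix(["a"], ["m"], np.array([[1.0]]))
        with pytest.raises(ModelError):
            gaussian_kernel(geno, h=0.0)


class TestRKHS:
    def test_identity_kernel_leaves_unphenotyped_at_zero(self):
        ids = [f"s{i}" for i in range(30)]
        K = RelationshipMatrix(ids, np.eye(30), "K")
        rng = np.random.default_rng(9)
        y = rng.standard_normal(20)
        fit = fit_rkhs(y, K, np.array(ids[:20]),
                       mcmc=McmcSettings(3000, 1000, 2, seed=1))
        unobs = fit.genetic_values.loc[ids[20:]]
        assert np.abs(unobs).max() < 0.05

    def test_duplicated_individual_gets_equal_values(self):
        rng = np.random.default_rng(10)
        dos = rng.integers(0, 3, size=(25, 60)).astype(float)
        dos[1] = dos[0]
        ids = [f"s{i}" for i in range(25)]
        geno = GenotypeMatrix(ids, [f"m{j}" for j in range(60)], dos)
        K = gaussian_kernel(geno)
        y = rng.standard_normal(25)
        y[1] = y[0]
        fit = fit_rkhs(y, K, np.array(ids), mcmc=McmcSettings(6000, 2000, 2, seed=2))
        delta = abs(fit.genetic_values.iloc[0] - fit.genetic_values.iloc[1])
        mc_se = fit.value_samples[:, :2].std(axis=0).max() / np.sqrt(
            fit.value_samples.shape[0]
        )
        assert delta < 3 * mc_se + 1e-3


class TestGEBV:
    def test_zero_effects_give_zero_gebv(self):
        rng = np.random.default_rng(11)
        geno, _, _, y = _sim_markers(rng, 30, 10, 2, 0.5)
        eff = fit_brr(y, geno, mcmc=McmcSettings(1000, 500, 5, seed=1))
        eff.effects = np.zeros(10)
        assert np.all(gebv_from_effects(eff, geno) == 0)

    def test_single_marker_indicator_coding(self):
        geno = GenotypeMatrix(list("abc"), ["m"], np.array([[0.0], [1.0], [2.0]]))
        rng = np.random.default_rng(12)
        eff = fit_brr(np.array([0.1, 0.0, -0.1]), geno,
                      mcmc=McmcSettings(1000, 500, 5, seed=1))
        eff.effects = np.array([1.0])
        np.testing.assert_allclose(
            gebv_from_effects(eff, geno).to_numpy(), [-1.0, 0.0, 1.0]
        )

    def test_markerwise_equals_matrix_path(self):
        rng = np.random.default_rng(13)
        geno, _, _, y = _sim_markers(rng, 40, 25, 5, 0.5)
        eff = fit_brr(y, geno, mcmc=McmcSettings(1000, 500, 5, seed=4))
        matrix_path = gebv_from_effects(eff, geno).to_numpy()
        loop_path = np.zeros(40)
        for j in range(25):
            loop_path += (geno.dosages[:, j] - 1.0) * eff.effects[j]
        np.testing.assert_allclose(matrix_path, loop_path, atol=1e-12)

    def test_marker_mismatch_fatal(self):
        rng = np.random.default_rng(14)
        geno, _, _, y = _sim_markers(rng, 30, 10, 2, 0.5)
        eff = fit_brr(y, geno, mcmc=McmcSettings(1000, 500, 5, seed=1))
        other = geno.subset(marker_ids=geno.markers[:5])
        with pytest.raises(ModelError, match="marker sets differ"):
            gebv_from_effects(eff, other)


class TestConvergenceDiagnostics:
    def test_iid_chains_rarely_flagged(self):
        rng = np.random.default_rng(15)
        flagged = 0
        for _ in range(1000):
            z = geweke_z(rng.standard_normal(200))
            flagged += abs(z) > 3
        assert flagged / 1000 < 0.01

    def test_drifting_chain_flagged(self):
        chain = np.linspace(0, 5, 300) + np.random.default_rng(16).normal(0, 0.1, 300)
        diag = convergence_check({"drift": chain})[0]
        assert diag.flagged

    def test_constant_chain_degenerate(self):
        diag = convergence_check({"const": np.ones(100)})[0]
        assert diag.degenerate and diag.flagged

    def test_trace_plots_written(self, tmp_path):
        rng = np.random.default_rng(17)
        convergence_check(
            {"a": rng.standard_normal(100), "b": rng.standard_normal(100)},
            report_dir=tmp_path,
        )
        assert (tmp_path / "trace_plots.png").exists()
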