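"""Mixed models: MME/GLS equivalence, REML behaviour, heritability, type-B, LRT."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import gls_blup_oracle
from sprucegs._errors import ModelError
from sprucegs.lmm import (
    ModelSpec,
    VarianceComponents,
    _LinearCovarianceREML,
    adjust_phenotypes,
    fit_reml,
    fit_single_kinship,
    heritability,
    lrt_type_b_vs_one,
    solve_mme,
    type_b_correlation,
)
from sprucegs.relationship import RelationshipMatrix, a_matrix, g_matrix, invert_relmatrix
from sprucegs.simdata import (
    PhenotypeTable,
    SimConfig,
    drop_genotypes,
    make_diallel_pedigree,
    simulate_phenotypes,
    simulate_trial,
)


def _random_instance(rng, n_fixed=2, n_ind=8, n_obs=14):
    X = np.column_stack([np.ones(n_obs), rng.standard_normal((n_obs, n_fixed - 1))])
    Z = np.zeros((n_obs, n_ind))
    Z[np.arange(n_obs), rng.integers(0, n_ind, n_obs)] = 1.0
    B = rng.standard_normal((n_ind, n_ind + 3))
    K = B @ B.T / (n_ind + 3) + 0.5 * np.eye(n_ind)
    y = rng.standard_normal(n_obs) * 2 + X @ rng.standard_normal(n_fixed)
    sigma_a2 = rng.uniform(0.5, 2.0)
    sigma_e2 = rng.uniform(0.5, 2.0)
    return X, Z, y, K, sigma_a2, sigma_e2


class TestSolveMME:
    def test_infinite_shrinkage_drives_blups_to_zero(self):
        rng = np.random.default_rng(0)
        X, Z, y, K, _, _ = _random_instance(rng)
        ids = [f"i{k}" for k in range(K.shape[0])]
        K_inv = invert_relmatrix(RelationshipMatrix(ids, np.eye(len(ids)), "A"))
        _, u = solve_mme(X, Z, y, K_inv, alpha=1e8)
        assert np.abs(u).max() < 1e-5

    def test_equals_gls_blup_oracle_on_toy(self):
        """2 founders + 4 offspring with printed phenotypes."""
        ped_rows = [
            ("A", "0", "0", 0, ""),
            ("B", "0", "0", 0, ""),
            ("c", "A", "B", 1, "site1"),
            ("d", "A", "B", 1, "site1"),
            ("e", "A", "B", 1, "site1"),
            ("f", "A", "B", 1, "site1"),
        ]
        ped = pd.DataFrame(
            ped_rows, columns=["id", "sire", "dam", "generation", "site"]
        )
        from sprucegs.simdata import Pedigree

        A = a_matrix(Pedigree(ped))
        y = np.array([1.2, -0.3, 0.8, 2.1])
        X = np.ones((4, 1))
        Z = np.zeros((4, 6))
        Z[np.arange(4), [2, 3, 4, 5]] = 1.0
        sigma_a2, sigma_e2 = 1.3, 0.9
        beta_o, u_o = gls_blup_oracle(X, Z, y, A.values, sigma_a2, sigma_e2)
        beta, u = solve_mme(X, Z, y, invert_relmatrix(A), sigma_e2 / sigma_a2)
        np.testing.assert_allclose(beta, beta_o, atol=1e-8)
        np.testing.assert_allclose(u, u_o, atol=1e-8)

    def test_property_random_instances_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            X, Z, y, K, sa2, se2 = _random_instance(rng)
            ids = [f"i{k}" for k in range(K.shape[0])]
            Krm = RelationshipMatrix(ids, K, "G")
            beta_o, u_o = gls_blup_oracle(X, Z, y, K, sa2, se2)
            beta, u = solve_mme(X, Z, y, invert_relmatrix(Krm), se2 / sa2)
            np.testing.assert_allclose(beta, beta_o, atol=1e-8)
            np.testing.assert_allclose(u, u_o, atol=1e-8)

    def test_duplicate_row_equals_double_weight(self):
        """Duplicating an observation row reproduces the normal-equations
        identity: the solution equals the de-duplicated system with that
        row's X'X/X'y contributions counted twice."""
        rng = np.random.default_rng(7)
        X, Z, y, K, sa2, se2 = _random_instance(rng)
        ids = [f"i{k}" for k in range(K.shape[0])]
        Kinv = invert_relmatrix(RelationshipMatrix(ids, K, "G"))
        alpha = se2 / sa2
        Xd = np.vstack([X, X[:1]])
        Zd = np.vstack([Z, Z[:1]])
        yd = np.concatenate([y, y[:1]])
        beta_d, u_d = solve_mme(Xd, Zd, yd, Kinv, alpha)
        # weighted normal equations built directly
        w = np.ones(len(y))
        w[0] = 2.0
        Xw = X * w[:, None]
        Zw = Z * w[:, None]
        C = np.block(
            [[X.T @ Xw, (Zw.T @ X).T], [Zw.T @ X, Z.T @ Zw + Kinv.values * alpha]]
        )
        rhs = np.concatenate([Xw.T @ y, Zw.T @ y])
        sol = np.linalg.solve(C, rhs)
        np.testing.assert_allclose(
            np.concatenate([beta_d, u_d]), sol, atol=1e-8
        )

    def test_singular_system_raises_with_rank(self):
        X = np.ones((4, 2))  # collinear fixed effects
        Z = np.eye(4)
        Kinv = RelationshipMatrix([f"i{k}" for k in range(4)], np.eye(4), "A")
        with pytest.raises(ModelError, match="rank"):
            solve_mme(X, Z, np.arange(4.0), Kinv, 1.0)


class TestHeritability:
    @pytest.mark.parametrize(
        "additive, residual, expected",
        [
            (690.8, 5260.5, 0.12),  # growth trait, site 1, pedigree model
            (2.3, 3.2, 0.42),  # Pilodyn, site 1, pedigree model
            (1.0, 1.0, 0.5),
        ],
    )
    def test_printed_arithmetic(self, additive, residual, expected):
        vc = VarianceComponents(
            params={"additive": additive, "residual": residual},
            loglik=0.0, converged=True,
            param_names=("additive", "residual"),
        )
        h2, _ = heritability(vc)
        assert round(h2, 2) == expected

    def test_block_variance_excluded_from_denominator(self):
        vc = VarianceComponents(
            params={"additive": 1.0, "residual": 1.0, "block": 5.0},
            loglik=0.0, converged=True,
            param_names=("additive", "residual", "block"),
        )
        h2, _ = heritability(vc)
        assert h2 == pytest.approx(0.5)


class TestTypeB:
    def _vc(self, v1, v2, cov):
        return VarianceComponents(
            params={
                "additive_site1": v1, "additive_site2": v2, "additive_cov": cov,
            },
            loglik=0.0, converged=True,
        )

    def test_perfect_correlation(self):
        assert type_b_correlation(self._vc(2.0, 8.0, 4.0)) == pytest.approx(1.0)

    def test_zero_covariance(self):
        assert type_b_correlation(self._vc(2.0, 8.0, 0.0)) == 0.0

    def test_zero_variance_flagged(self):
        with pytest.raises(ModelError):
            type_b_correlation(self._vc(0.0, 8.0, 0.0))


class TestREML:
    def test_em_steps_never_decrease_loglik(self):
        rng = np.random.default_rng(3)
        n = 60
        B = rng.standard_normal((n, n + 5))
        K = B @ B.T / (n + 5)
        y = rng.multivariate_normal(np.zeros(n), 1.5 * K + np.eye(n))
        engine = _LinearCovarianceREML(
            y, np.ones((n, 1)), [K, np.eye(n)], ["additive", "residual"],
            ["var", "var"], {}, [float(n), float(n)],
        )
        theta = np.array([0.1, 3.0])
        lls = []
        for _ in range(15):
            ll, P, Py = engine._quantities(theta)
            lls.append(ll)
            theta = engine._em_step(theta, P, Py)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_zero_additive_variance_boundary(self):
        """Traits simulated without genetic signal estimate h² at the floor."""
        cfg = SimConfig(
            n_markers=200, n_qtl=50, n_parents=15, n_families=25,
            progeny_range=(4, 6), trait_specs=(("flat", 0.0, 0.0),), seed=21,
        )
        ped = make_diallel_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        A = a_matrix(ped)
        h2s = []
        for rep in range(5):
            cfg_r = dataclasses.replace(cfg, seed=100 + rep)
            pheno, _ = simulate_phenotypes(geno, ped, cfg_r)
            fit = fit_reml(pheno, A, ModelSpec(trait="flat", scope="site1"))
            h2s.append(heritability(fit.vc)[0])
        assert np.mean(h2s) <= 0.02

    def test_pedigree_and_genomic_kinship_share_code_path(self):
        """With dense markers on unrelated founders G -> I = A, and the two
        kinship matrices give nearly identical EBV rankings."""
        cfg = SimConfig(
            n_markers=5000, n_qtl=1000, n_parents=80, n_families=1,
            progeny_range=(1, 1), seed=13,
        )
        ped = make_diallel_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        founders = list(ped.founder_ids)
        geno_f = geno.subset(sample_ids=founders)
        G = g_matrix(geno_f)
        A = RelationshipMatrix(founders, np.eye(len(founders)), "A")
        rng = np.random.default_rng(5)
        g_true = rng.standard_normal(len(founders))
        y = g_true + rng.standard_normal(len(founders)) * 0.8
        fa = fit_single_kinship(y, np.array(founders), A, predict_ids=founders)
        fg = fit_single_kinship(y, np.array(founders), G, predict_ids=founders)
        r = np.corrcoef(fa.ebv.to_numpy(), fg.ebv.to_numpy())[0, 1]
        assert r >= 0.98


class TestAdjustPhenotypes:
    def test_per_site_standardization(self, small_trial, small_matrices):
        ped, geno, pheno, _ = small_trial
        A, _ = small_matrices
        fit = fit_reml(pheno, A, ModelSpec(trait="height", scope="joint"))
        yprime = adjust_phenotypes(pheno, fit)
        frame = pheno.frame.set_index("tree")
        for site in ("site1", "site2"):
            vals = yprime[frame["site"] == site]
            assert vals.mean() == pytest.approx(0.0, abs=1e-10)
            assert vals.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_injected_block_offset_removed(self):
        cfg = SimConfig(
            n_markers=300, n_qtl=100, n_parents=15, n_families=30,
            progeny_range=(5, 7), n_blocks_per_site=6,
            trait_specs=(("t", 0.3, 0.9),), seed=17,
        )
        ped, geno, pheno, _ = simulate_trial(cfg)
        frame = pheno.frame.copy()
        site1 = frame[frame["site"] == "site1"]
        target_block = site1["block"].iloc[0]
        sd = site1["t"].std()
        frame.loc[frame["block"] == target_block, "t"] += 10 * sd
        pheno2 = PhenotypeTable(frame, pheno.traits)
        A = a_matrix(ped)
        fit = fit_reml(pheno2, A, ModelSpec(trait="t", scope="site1"))
        yprime = adjust_phenotypes(pheno2, fit)
        blk = frame.set_index("tree")["block"]
        resid_mean = yprime[blk == target_block].mean()
        assert abs(resid_mean) < 0.5  # y' is per-site unit variance

    def test_zero_block_variance_reduces_to_zscore(self, small_trial, small_matrices):
        ped, geno, pheno, _ = small_trial
        A, _ = small_matrices
        fit = fit_reml(pheno, A, ModelSpec(trait="height", scope="joint"))
        no_block = dataclasses.replace(fit, block_effects={})
        yprime = adjust_phenotypes(pheno, no_block)
        frame = pheno.frame.set_index("tree")
        for site in ("site1", "site2"):
            sub = frame[frame["site"] == site]
            z = (sub["height"] - sub["height"].mean()) / sub["height"].std(ddof=0)
            np.testing.assert_allclose(
                yprime[sub.index].to_numpy(), z.to_numpy(), atol=1e-10
            )


class TestLRT:
    def test_identical_likelihoods_give_half(self):
        spec = ModelSpec(trait="t", scope="joint")
        vc = VarianceComponents(params={}, loglik=-10.0, converged=True)
        from sprucegs.lmm import ModelFit

        f = ModelFit(spec, vc, np.zeros(1), ("mean",), pd.DataFrame(), {}, np.array([]))
        stat, p = lrt_type_b_vs_one(f, f)
        assert stat == 0.0
        assert p == pytest.approx(0.5)

    def test_type_one_error_controlled_at_boundary(self):
        """Data simulated at r12 = 1: one-tailed mixture test rejects at <=
        ~5% nominal (allowing Monte Carlo slack)."""
        cfg = SimConfig(
            n_markers=200, n_qtl=100, n_parents=12, n_families=15,
            progeny_range=(4, 4), trait_specs=(("t", 0.35, 1.0),), seed=33,
        )
        ped = make_diallel_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        A = a_matrix(ped)
        rejections = 0
        n_reps = 200
        for rep in range(n_reps):
            cfg_r = dataclasses.replace(cfg, seed=1000 + rep)
            pheno, _ = simulate_phenotypes(geno, ped, cfg_r)
            full = fit_reml(pheno, A, ModelSpec(trait="t", scope="joint"))
            constrained = fit_reml(
                pheno, A,
                ModelSpec(trait="t", scope="joint", joint_covariance="corr1"),
            )
            stat = 2.0 * (full.vc.loglik - constrained.vc.loglik)
            if stat < 0:
                stat = 0.0
            from scipy import stats as sps

            p = 0.5 * sps.chi2.sf(stat, 1)
            rejections += p < 0.05
        assert rejections / n_reps <= 0.075

    def test_power_against_strong_gxe(self):
        """r12 simulated at 0.4 with ~1000 trees/site: the test detects it."""
        cfg = SimConfig(
            n_markers=400, n_qtl=200, n_parents=30, n_families=100,
            progeny_range=(9, 11), trait_specs=(("t", 0.25, 0.4),), seed=8,
        )
        ped = make_diallel_pedigree(cfg)
        geno = drop_genotypes(ped, cfg)
        A = a_matrix(ped)
        pvals = []
        for rep in range(3):
            cfg_r = dataclasses.replace(cfg, seed=2000 + rep)
            pheno, _ = simulate_phenotypes(geno, ped, cfg_r)
            full = fit_reml(pheno, A, ModelSpec(trait="t", scope="joint"))
            constrained = fit_reml(
                pheno, A,
                ModelSpec(trait="t", scope="joint", joint_covariance="corr1"),
            )
            _, p = lrt_type_b_vs_one(full, constrained)
            pvals.append(p)
        assert np.median(pvals) < 0.05
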