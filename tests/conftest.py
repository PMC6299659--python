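"""Shared fixtures: small synthetic trials reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sprucegs import relationship, simdata


@pytest.fixture(scope="session")
def small_cfg() -> simdata.SimConfig:
    """Desk-scale diallel: 20 parents, 40 families, ~400 trees, 2 traits."""
    return simdata.SimConfig(
        n_markers=600,
        n_qtl=150,
        n_parents=20,
        n_families=40,
        progeny_range=(4, 6),
        trait_specs=(("height", 0.4, 0.5), ("pilodyn", 0.5, 0.9)),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_trial(small_cfg):
    return simdata.simulate_trial(small_cfg)


@pytest.fixture(scope="session")
def small_matrices(small_trial):
    ped, geno, pheno, truth = small_trial
    return relationship.a_matrix(ped), relationship.g_matrix(geno)


@pytest.fixture()
def toy_pedigree() -> simdata.Pedigree:
    """Two founder pairs, full sibs, half sibs and a third generation."""
    rows = [
        ("F1", "0", "0", 0, ""),
        ("F2", "0", "0", 0, ""),
        ("F3", "0", "0", 0, ""),
        ("F4", "0", "0", 0, ""),
        ("O1", "F1", "F2", 1, "site1"),  # full sibs O1, O2
        ("O2", "F1", "F2", 1, "site1"),
        ("O3", "F1", "F3", 1, "site1"),  # half sib of O1/O2 via F1
        ("O4", "F3", "F4", 1, "site2"),
        ("G1", "O1", "O4", 2, "site1"),  # third generation
        ("G2", "O2", "O4", 2, "site2"),
    ]
    return simdata.Pedigree(
        pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "site"])
    )


def gls_blup_oracle(X, Z, y, K, sigma_a2, sigma_e2):
    """Direct GLS/BLUP from the full covariance V = ZKZ'σ²_a + Iσ²_e.

    Independent of the mixed-model-equation path: β̂ = (X'V⁻¹X)⁻¹X'V⁻¹y and
    û = σ²_a K Z' V⁻¹ (y − Xβ̂).
    """
    n = len(y)
    V = sigma_a2 * (Z @ K @ Z.T) + sigma_e2 * np.eye(n)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    u = sigma_a2 * (K @ Z.T @ (Vinv @ (y - X @ beta)))
    return beta, u
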