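"""Linear mixed models for pedigree- and marker-based breeding-value prediction.

The joint-site animal model is

    y = Xβ + W b(s) + Z a + e

with fixed β (grand mean, site), random post-block-within-site effects
b(s) ~ N(0, I σ²_b), additive effects a, and heteroscedastic residuals.
Three additive covariance families are supported:

* single-site: a ~ N(0, K σ²_a) on the trees of one site;
* joint unstructured: per-site effects with across-site covariance
  a ~ N(0, Σ ⊗ K), Σ = [[σ²_a1, σ_a12], [σ_a12, σ²_a2]];
* joint homogeneous + site×additive: a common additive effect plus an
  independent per-site interaction term, pooled residual.

Variance components are estimated by average-information (AI) REML with
expectation–maximization fallback steps; BLUPs/EBVs come from the mixed
model equations (equivalently the GLS identity û = Cov(u, y) V⁻¹ (y − Xβ̂)),
including unphenotyped relatives.  K may be the pedigree A matrix (ABLUP)
or a genomic G matrix (GBLUP) — the code path is identical.

A fast two-component path (one kinship + residual, used heavily in
cross-validation) profiles the likelihood on the variance ratio after a
one-time eigendecomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import optimize, stats

from ._errors import ModelError
from .relationship import RelationshipMatrix
from .simdata import PhenotypeTable

log = logging.getLogger(__name__)

VARIANCE_FLOOR_FRACTION = 1e-8  # of phenotypic variance
MAX_ITER = 200
LOGLIK_TOL = 1e-6
PARAM_TOL = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    trait: str
    kinship: str = "A"  # informational: {"A", "G"}
    scope: str = "joint"  # {"site1", "site2", "joint"}
    #: across-site additive covariance; only meaningful for joint scope
    #: ("unstructured", "homogeneous_plus_sa", or "corr1")
    joint_covariance: str = "unstructured"
    random_blocks: bool = True

    def __post_init__(self) -> None:
        if self.scope not in ("site1", "site2", "joint"):
            raise ModelError(f"unknown scope {self.scope!r}")
        if self.joint_covariance not in (
            "unstructured", "homogeneous_plus_sa", "corr1"
        ):
            raise ModelError(
                f"unknown joint covariance {self.joint_covariance!r}"
            )


@dataclass
class VarianceComponents:
    """REML estimates: named components, log-likelihood, asymptotic covariance."""

    params: dict[str, float]
    loglik: float
    converged: bool
    param_names: tuple[str, ...] = ()
    asymp_cov: np.ndarray | None = None  # inverse AI matrix at convergence
    n_iter: int = 0

    def __getitem__(self, key: str) -> float:
        return self.params[key]

    def cov_of(self, names: tuple[str, ...]) -> np.ndarray:
        """Asymptotic covariance sub-matrix for the named parameters."""
        if self.asymp_cov is None:
            return np.full((len(names), len(names)), np.nan)
        pos = {n: i for i, n in enumerate(self.param_names)}
        idx = [pos[n] for n in names]
        return self.asymp_cov[np.ix_(idx, idx)]


@dataclass
class ModelFit:
    """A converged (or best-effort) REML fit with BLUPs."""

    spec: ModelSpec
    vc: VarianceComponents
    beta: np.ndarray
    fixed_names: tuple[str, ...]
    ebv: pd.DataFrame  # index: all K ids; columns: per-site EBVs and/or "mean"
    block_effects: dict[str, float]
    obs_ids: np.ndarray
    alpha: float | None = None  # σ²_e / σ²_a used in MME form, where defined


# ---------------------------------------------------------------------------
# Core AI-REML engine for V(θ) = Σ_k θ_k C_k
# ---------------------------------------------------------------------------

class _LinearCovarianceREML:
    """AI-REML for covariance linear in its parameters: V(θ) = Σ θ_k C_k.

    ``kinds[k]`` is "var" (bounded below by a floor) or "cov" (free sign,
    clamped so the implied correlation stays inside (−1, 1)); ``cov_pair``
    names the two variance components a covariance parameter links.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        components: list[np.ndarray],
        names: list[str],
        kinds: list[str],
        cov_pairs: dict[int, tuple[int, int]] | None = None,
        em_ranks: list[float] | None = None,
    ) -> None:
        self.y = y
        self.X = X
        self.C = components
        self.names = names
        self.kinds = kinds
        self.cov_pairs = cov_pairs or {}
        self.n, self.p = X.shape
        self.floor = VARIANCE_FLOOR_FRACTION * float(np.var(y))
        self.em_ranks = em_ranks or [float(self.n)] * len(components)

    # -- likelihood machinery -------------------------------------------------

    def _build_v(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for t, C in zip(theta, self.C):
            V += t * C
        return V

    def _valid(self, theta: np.ndarray) -> bool:
        for k, kind in enumerate(self.kinds):
            if kind == "var" and theta[k] < self.floor:
                return False
            if kind == "cov":
                i, j = self.cov_pairs[k]
                if abs(theta[k]) > (1 - 1e-9) * np.sqrt(theta[i] * theta[j]):
                    return False
        return True

    def _project(self, theta: np.ndarray) -> np.ndarray:
        theta = theta.copy()
        for k, kind in enumerate(self.kinds):
            if kind == "var":
                theta[k] = max(theta[k], self.floor)
        for k, kind in enumerate(self.kinds):
            if kind == "cov":
                i, j = self.cov_pairs[k]
                bound = (1 - 1e-6) * np.sqrt(theta[i] * theta[j])
                theta[k] = np.clip(theta[k], -bound, bound)
        return theta

    def _quantities(self, theta: np.ndarray):
        """Return (loglik, P, Py) or None if V is not positive definite."""
        V = self._build_v(theta)
        # dpotrf/dpotri: factor + in-place inverse at ~n^3 total
        c, info = scipy.linalg.lapack.dpotrf(V, lower=1, overwrite_a=1)
        if info != 0:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv, info = scipy.linalg.lapack.dpotri(c, lower=1, overwrite_c=1)
        if info != 0:
            return None
        Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
        VinvX = Vinv @ self.X
        XtVinvX = self.X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return None
        B = np.linalg.solve(XtVinvX, VinvX.T)
        P = Vinv
        P -= VinvX @ B  # in place: Vinv buffer becomes P
        Py = P @ self.y
        loglik = -0.5 * (logdet_v + logdet_x + float(self.y @ Py))
        return loglik, P, Py

    def loglik(self, theta: np.ndarray) -> float:
        q = self._quantities(theta)
        return -np.inf if q is None else q[0]

    # -- updates --------------------------------------------------------------

    def _score_ai(self, P: np.ndarray, Py: np.ndarray):
        k = len(self.C)
        score = np.empty(k)
        w = [C @ Py for C in self.C]
        P_flat = P.ravel()
        for i in range(k):
            tr = float(P_flat @ self.C[i].ravel())  # tr(PC), both symmetric
            score[i] = -0.5 * (tr - float(Py @ w[i]))
        AI = np.empty((k, k))
        Pw = [P @ wi for wi in w]
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(w[i] @ Pw[j])
        return score, AI

    def _em_step(self, theta: np.ndarray, P: np.ndarray, Py: np.ndarray) -> np.ndarray:
        """Monotone EM update for the variance parameters (covariances held)."""
        new = theta.copy()
        for k, kind in enumerate(self.kinds):
            if kind != "var":
                continue
            tr = float(np.sum(P * self.C[k]))
            quad = float(Py @ (self.C[k] @ Py))
            new[k] = theta[k] + theta[k] ** 2 * (quad - tr) / self.em_ranks[k]
        return self._project(new)

    def fit(self, start: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
        theta = self._project(np.asarray(start, dtype=float))
        q = self._quantities(theta)
        if q is None:
            raise ModelError("starting covariance matrix not positive definite")
        ll, P, Py = q
        AI_last = np.eye(len(theta))
        converged = False
        flat_count = 0
        it = 0
        for it in range(1, MAX_ITER + 1):
            score, AI = self._score_ai(P, Py)
            AI_last = AI
            # active set: variance parameters pinned at the floor with a
            # negative score stay there instead of stalling the update
            free = np.array(
                [
                    not (
                        self.kinds[k] == "var"
                        and theta[k] <= 1.01 * self.floor
                        and score[k] < 0
                    )
                    for k in range(len(theta))
                ]
            )
            if not free.any():
                converged = True
                break
            delta = np.zeros(len(theta))
            idx = np.where(free)[0]
            try:
                delta[idx] = np.linalg.solve(
                    AI[np.ix_(idx, idx)] + 1e-10 * np.eye(len(idx)), score[idx]
                )
            except np.linalg.LinAlgError:
                delta[idx] = score[idx]
            # AI step with step-halving; EM fallback if no improvement
            improved = False
            step = 1.0
            for _ in range(12):
                cand = self._project(theta + step * delta)
                qc = self._quantities(cand)
                if qc is not None and qc[0] >= ll - 1e-10:
                    theta_new, (ll_new, P_new, Py_new) = cand, qc
                    improved = True
                    break
                step *= 0.5
            if not improved:
                cand = self._em_step(theta, P, Py)
                qc = self._quantities(cand)
                if qc is None or qc[0] < ll - 1e-8 or np.allclose(cand, theta):
                    # no direction improves: at a (possibly boundary) maximum
                    converged = True
                    break
                theta_new, (ll_new, P_new, Py_new) = cand, qc
            rel = np.max(
                np.abs(theta_new - theta) / np.maximum(np.abs(theta), self.floor)
            )
            dll = ll_new - ll
            theta, ll, P, Py = theta_new, ll_new, P_new, Py_new
            if abs(dll) < LOGLIK_TOL and rel < PARAM_TOL:
                converged = True
                break
            if abs(dll) < LOGLIK_TOL:
                flat_count += 1
                if flat_count >= 3:  # likelihood flat along a weak direction
                    converged = True
                    break
            else:
                flat_count = 0
        if not converged:
            log.warning("AI-REML did not converge in %d iterations", it)
        return theta, ll, AI_last, converged, it


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def _design(pheno: PhenotypeTable, trait: str, scope: str):
    """Observation vectors and incidence structures for one model scope."""
    frame = pheno.frame
    if scope in ("site1", "site2"):
        frame = frame[frame["site"] == scope]
        if len(frame) == 0:
            raise ModelError(f"no observations at {scope}")
    frame = frame.dropna(subset=[trait])
    y = frame[trait].to_numpy(dtype=float)
    sites = sorted(frame["site"].unique())
    site_codes = np.array([sites.index(s) for s in frame["site"]])
    if len(sites) > 1:
        X = np.column_stack(
            [np.ones(len(frame))]
            + [(site_codes == s).astype(float) for s in range(1, len(sites))]
        )
        fixed_names = ("mean",) + tuple(f"site:{s}" for s in sites[1:])
    else:
        X = np.ones((len(frame), 1))
        fixed_names = ("mean",)
    blocks = frame["block"].to_numpy()
    block_levels = sorted(set(blocks))
    W = np.zeros((len(frame), len(block_levels)))
    for j, b in enumerate(block_levels):
        W[:, j] = blocks == b
    return frame, y, X, fixed_names, site_codes, sites, W, block_levels


def _start_values(y: np.ndarray, names: list[str]) -> np.ndarray:
    s2 = float(np.var(y))
    start = []
    for n in names:
        if n.startswith("additive_cov"):
            start.append(0.2 * s2)
        elif n.startswith("additive") or n.startswith("site_by_additive"):
            start.append(0.3 * s2)
        elif n == "block":
            start.append(0.1 * s2)
        else:  # residual
            start.append(0.6 * s2)
    return np.array(start)


def fit_reml(
    pheno: PhenotypeTable,
    K: RelationshipMatrix,
    spec: ModelSpec,
    start: np.ndarray | None = None,
) -> ModelFit:
    """Fit the animal model by AI-REML and return components plus EBVs.

    EBVs are reported for every id in ``K`` (including unphenotyped parents).
    For the joint unstructured model, per-site EBVs and their mean (the
    reference breeding values used by cross-validation) are returned.
    """
    frame, y, X, fixed_names, site_codes, sites, W, block_levels = _design(
        pheno, spec.trait, spec.scope
    )
    if len(y) < 3:
        raise ModelError("too few observations to estimate variance components")
    pos = {s: i for i, s in enumerate(K.ids)}
    missing = [t for t in frame["tree"] if t not in pos]
    if missing:
        raise ModelError(
            f"{len(missing)} phenotyped trees missing from {K.kind} matrix"
        )
    obs_idx = np.array([pos[t] for t in frame["tree"]])
    Kobs = K.values[np.ix_(obs_idx, obs_idx)]
    n = len(y)

    components: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    cov_pairs: dict[int, tuple[int, int]] = {}
    em_ranks: list[float] = []

    joint = spec.scope == "joint" and len(sites) > 1
    if joint and spec.joint_covariance == "unstructured":
        S1 = (site_codes == 0).astype(float)
        S2 = (site_codes == 1).astype(float)
        components += [
            Kobs * np.outer(S1, S1),
            Kobs * np.outer(S2, S2),
            Kobs * (np.outer(S1, S2) + np.outer(S2, S1)),
        ]
        names += ["additive_site1", "additive_site2", "additive_cov"]
        kinds += ["var", "var", "cov"]
        cov_pairs[2] = (0, 1)
        em_ranks += [float(n), float(n), float(n)]
    elif joint and spec.joint_covariance == "homogeneous_plus_sa":
        same_site = (site_codes[:, None] == site_codes[None, :]).astype(float)
        components += [Kobs, Kobs * same_site]
        names += ["additive", "site_by_additive"]
        kinds += ["var", "var"]
        em_ranks += [float(n), float(n)]
    elif joint and spec.joint_covariance == "corr1":
        # rank-1 across-site structure (r12 fixed at 1, per-site variances
        # free): handled by an outer profile over the site-2/site-1 scaling,
        # each inner problem being linear in its parameters
        pass
    else:
        components += [Kobs]
        names += ["additive"]
        kinds += ["var"]
        em_ranks += [float(n)]

    if spec.random_blocks:
        components.append(W @ W.T)
        names.append("block")
        kinds.append("var")
        em_ranks.append(float(len(block_levels)))

    if joint and spec.joint_covariance in ("unstructured", "corr1"):
        for s, lab in enumerate(sites):
            Ss = (site_codes == s).astype(float)
            components.append(np.diag(Ss))
            names.append(f"residual_{lab}")
            kinds.append("var")
            em_ranks.append(float(Ss.sum()))
    else:
        components.append(np.eye(n))
        names.append("residual")
        kinds.append("var")
        em_ranks.append(float(n))

    if joint and spec.joint_covariance == "corr1":
        # profile REML over rho = sqrt(sigma_a2(site2)/sigma_a2(site1)); for a
        # fixed rho the additive covariance c1^2*(S11 + rho^2 S22 + rho S12)
        # is linear in c1^2, so the linear engine fits the inner problem
        S1 = (site_codes == 0).astype(float)
        S2 = (site_codes == 1).astype(float)
        K11 = Kobs * np.outer(S1, S1)
        K22 = Kobs * np.outer(S2, S2)
        K12 = Kobs * (np.outer(S1, S2) + np.outer(S2, S1))
        tail_names = names[:]
        inner_names = ["additive"] + tail_names
        inner_kinds = ["var"] + kinds[:]
        inner_ranks = [float(n)] + em_ranks[:]
        warm: dict[str, np.ndarray] = {}

        def fit_at(log_rho: float):
            rho = np.exp(log_rho)
            C = K11 + rho**2 * K22 + rho * K12
            engine = _LinearCovarianceREML(
                y, X, [C] + components, inner_names, inner_kinds, {}, inner_ranks
            )
            theta0 = warm.get("theta")
            if theta0 is None:
                theta0 = _start_values(y, inner_names)
            theta, ll, AI, conv, n_it = engine.fit(theta0)
            warm["theta"] = theta
            return ll, theta, AI, conv, n_it, engine, rho

        res = optimize.minimize_scalar(
            lambda lr: -fit_at(lr)[0], bounds=(-2.5, 2.5), method="bounded",
            options={"xatol": 0.05},
        )
        ll, theta_in, AI, converged, n_iter, engine, rho = fit_at(float(res.x))
        c1 = theta_in[0]
        theta = np.concatenate([[c1, c1 * rho**2, c1 * rho], theta_in[1:]])
        names = ["additive_site1", "additive_site2", "additive_cov"] + tail_names
        theta_engine = theta_in
        AI = None
    else:
        engine = _LinearCovarianceREML(
            y, X, components, names, kinds, cov_pairs, em_ranks
        )
        theta0 = (
            np.asarray(start, float) if start is not None else _start_values(y, names)
        )
        theta, ll, AI, converged, n_iter = engine.fit(theta0)
        theta_engine = theta

    asymp = None
    if AI is not None:
        try:
            asymp = np.linalg.inv(AI + 1e-12 * np.eye(len(theta)))
        except np.linalg.LinAlgError:
            asymp = None
    vc = VarianceComponents(
        params=dict(zip(names, theta)),
        loglik=ll,
        converged=converged,
        param_names=tuple(names),
        asymp_cov=asymp,
        n_iter=n_iter,
    )

    # --- GLS fixed effects and BLUPs at converged components -----------------
    q = engine._quantities(theta_engine)
    if q is None:
        raise ModelError("converged covariance matrix not positive definite")
    _, P, Py = q
    V = engine._build_v(theta_engine)
    c, low = scipy.linalg.cho_factor(V, lower=True)
    Vinv_y_minus = None
    Vinv = scipy.linalg.cho_solve((c, low), np.eye(n))
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ (Vinv @ y))
    resid = y - X @ beta
    Vinv_r = Vinv @ resid
    del Vinv_y_minus

    # block BLUPs
    block_effects: dict[str, float] = {}
    if spec.random_blocks:
        sb2 = vc["block"]
        b_blup = sb2 * (W.T @ Vinv_r)
        block_effects = dict(zip(block_levels, b_blup))

    # additive EBVs for every id in K
    Kcross = K.values[:, obs_idx]  # (n_all, n_obs)
    ebv_cols: dict[str, np.ndarray] = {}
    if joint and spec.joint_covariance in ("unstructured", "corr1"):
        Sg = np.array(
            [
                [vc["additive_site1"], vc["additive_cov"]],
                [vc["additive_cov"], vc["additive_site2"]],
            ]
        )
        for s, lab in enumerate(sites):
            colscale = Sg[s, site_codes]  # Σ[s, site of obs j]
            ebv_cols[f"ebv_{lab}"] = (Kcross * colscale) @ Vinv_r
        ebv_cols["ebv_mean"] = 0.5 * (
            ebv_cols[f"ebv_{sites[0]}"] + ebv_cols[f"ebv_{sites[1]}"]
        )
    elif joint and spec.joint_covariance == "homogeneous_plus_sa":
        sa2 = vc["additive"]
        ebv_cols["ebv_mean"] = sa2 * (Kcross @ Vinv_r)
    else:
        sa2 = vc["additive"]
        col = sa2 * (Kcross @ Vinv_r)
        ebv_cols["ebv_mean"] = col
        if spec.scope in ("site1", "site2"):
            ebv_cols[f"ebv_{spec.scope}"] = col

    ebv = pd.DataFrame(ebv_cols, index=K.ids)

    resid_name = "residual" if "residual" in vc.params else f"residual_{sites[0]}"
    add_name = "additive_site1" if "additive_site1" in vc.params else "additive"
    alpha = (
        vc[resid_name] / vc[add_name] if vc[add_name] > 0 else None
    )
    return ModelFit(
        spec=spec,
        vc=vc,
        beta=beta,
        fixed_names=fixed_names,
        ebv=ebv,
        block_effects=block_effects,
        obs_ids=frame["tree"].to_numpy(),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Henderson mixed-model equations
# ---------------------------------------------------------------------------

def solve_mme(
    X: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    K_inv: RelationshipMatrix,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve [[X'X, X'Z], [Z'X, Z'Z + K⁻¹α]] [b, u] = [X'y, Z'y].

    ``alpha = σ²_e / σ²_a``.  Raises on a singular coefficient matrix with a
    rank diagnostic.
    """
    if alpha <= 0:
        raise ModelError("alpha must be positive")
    Ainv = K_inv.values
    p, q = X.shape[1], Z.shape[1]
    if Ainv.shape != (q, q):
        raise ModelError(
            f"K_inv dimension {Ainv.shape} does not match Z columns ({q})"
        )
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + Ainv * alpha])
    C = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym")
    except np.linalg.LinAlgError as exc:
        raise ModelError(
            f"singular MME coefficient matrix: rank {np.linalg.matrix_rank(C)} "
            f"< {C.shape[0]}"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise ModelError(
            f"singular MME coefficient matrix: rank {np.linalg.matrix_rank(C)} "
            f"< {C.shape[0]}"
        )
    return sol[:p], sol[p:]


# ---------------------------------------------------------------------------
# Phenotype adjustment (block removal + per-site standardization)
# ---------------------------------------------------------------------------

def adjust_phenotypes(pheno: PhenotypeTable, fit: ModelFit) -> pd.Series:
    """y′ = y − block BLUP, then per-site centering/scaling to mean 0, var 1.

    Returns a Series indexed like ``pheno.frame`` (one adjusted value per
    phenotyped tree of the fit's trait).
    """
    trait = fit.spec.trait
    frame = pheno.frame.dropna(subset=[trait])
    y = frame[trait].to_numpy(dtype=float)
    block_adj = np.array([fit.block_effects.get(b, 0.0) for b in frame["block"]])
    yprime = y - block_adj
    out = np.empty_like(yprime)
    for site in frame["site"].unique():
        m = (frame["site"] == site).to_numpy()
        if m.sum() < 2:
            raise ModelError(f"site {site!r} has fewer than 2 trees; cannot standardize")
        v = yprime[m]
        sd = v.std(ddof=0)
        if sd == 0:
            raise ModelError(f"site {site!r} has zero phenotypic variance")
        out[m] = (v - v.mean()) / sd
    return pd.Series(out, index=frame["tree"].to_numpy(), name=f"{trait}_adj")


# ---------------------------------------------------------------------------
# Heritability, type-B correlation, LRT
# ---------------------------------------------------------------------------

def heritability(
    vc: VarianceComponents, site: str | None = None, include_sa: bool = False
) -> tuple[float, float]:
    """Narrow-sense h² = σ²_a / (σ²_a + σ²_e) with a delta-method SE.

    The denominator excludes the block variance (matching the study's printed
    arithmetic); for the homogeneous joint model the site×additive component
    is excluded unless ``include_sa``.
    """
    p = vc.params
    if "additive_site1" in p and site in ("site1", "site2"):
        a_name, e_name = f"additive_{site}", f"residual_{site}"
    elif "additive" in p:
        a_name = "additive"
        e_name = "residual" if "residual" in p else None
        if e_name is None:
            raise ModelError("pooled residual not available for h²")
    else:
        raise ModelError("specify site='site1'|'site2' for an unstructured fit")
    sa = p[a_name]
    se2 = p[e_name]
    extra = p.get("site_by_additive", 0.0) if include_sa else 0.0
    denom = sa + se2 + extra
    if denom <= 0:
        raise ModelError("zero phenotypic variance: h² undefined")
    h2 = sa / denom
    grad_names = (a_name, e_name)
    C = vc.cov_of(grad_names)
    g = np.array([se2 / denom**2, -sa / denom**2])
    var = float(g @ C @ g)
    se = np.sqrt(var) if np.isfinite(var) and var >= 0 else np.nan
    return h2, se


def type_b_correlation(vc: VarianceComponents) -> float:
    """Across-site additive correlation r₁₂ = σ_a12 / √(σ²_a1 σ²_a2)."""
    p = vc.params
    for name in ("additive_site1", "additive_site2", "additive_cov"):
        if name not in p:
            raise ModelError("type-B requires an unstructured joint fit")
    v1, v2 = p["additive_site1"], p["additive_site2"]
    if v1 <= 0 or v2 <= 0:
        raise ModelError("a site additive variance is zero: type-B undefined")
    r = p["additive_cov"] / np.sqrt(v1 * v2)
    return float(np.clip(r, -1.0, 1.0))


def lrt_type_b_vs_one(
    full: ModelFit, constrained: ModelFit
) -> tuple[float, float]:
    """One-tailed boundary LRT of r₁₂ = 1.

    The constrained fit is the homogeneous correlation-1 structure (a single
    common additive effect across sites).  The statistic 2(ℓ_full − ℓ_c) is
    referred to a 50:50 mixture of χ²₀ and χ²₁.
    """
    stat = 2.0 * (full.vc.loglik - constrained.vc.loglik)
    if stat < -1e-4:
        raise ModelError(
            f"constrained log-likelihood exceeds full by {-stat / 2:.3g}: "
            "optimizer failure, refit with better starting values"
        )
    stat = max(stat, 0.0)
    p = 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p


# ---------------------------------------------------------------------------
# Fast two-component path (kinship + residual), used by cross-validation
# ---------------------------------------------------------------------------

@dataclass
class KinshipFitResult:
    sigma_a2: float
    sigma_e2: float
    loglik: float
    beta: np.ndarray
    h2: float
    ebv: pd.Series  # indexed by predict ids


def fit_single_kinship(
    y: np.ndarray,
    obs_ids: np.ndarray,
    K: RelationshipMatrix,
    predict_ids: np.ndarray | None = None,
    X: np.ndarray | None = None,
) -> KinshipFitResult:
    """REML for y = Xβ + a + e with a ~ N(0, K σ²_a), e ~ N(0, I σ²_e).

    Profiles the REML likelihood on the ratio λ = σ²_a/σ²_e after one
    eigendecomposition of the observed-block of K, then BLUP-predicts
    ``predict_ids`` (default: every id in K) through their kinship rows.
    """
    pos = {s: i for i, s in enumerate(K.ids)}
    try:
        obs_idx = np.array([pos[t] for t in obs_ids])
    except KeyError as exc:
        raise ModelError(f"observation id missing from {K.kind} matrix: {exc}") from exc
    Kobs = K.values[np.ix_(obs_idx, obs_idx)]
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    p = X.shape[1]

    d, U = np.linalg.eigh(Kobs)
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        D = lam * d + 1.0
        XtDX = (Xr / D[:, None]).T @ Xr
        try:
            beta = np.linalg.solve(XtDX, (Xr / D[:, None]).T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        q = float(r @ (r / D))
        sign, logdet_x = np.linalg.slogdet(XtDX)
        if sign <= 0 or q <= 0:
            return np.inf
        return 0.5 * (
            np.sum(np.log(D)) + logdet_x + (n - p) * np.log(q)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    D = lam * d + 1.0
    XtDX = (Xr / D[:, None]).T @ Xr
    beta = np.linalg.solve(XtDX, (Xr / D[:, None]).T @ yr)
    r = yr - Xr @ beta
    sigma_e2 = float(r @ (r / D)) / (n - p)
    sigma_a2 = lam * sigma_e2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)

    # V⁻¹(y − Xβ) = U (r / (σ²_e D));  û = σ²_a K[pred, obs] V⁻¹ r
    vinv_r = U @ (r / (sigma_e2 * D))
    if predict_ids is None:
        predict_ids = K.ids
    pred_idx = np.array([pos[t] for t in predict_ids])
    ucap = sigma_a2 * (K.values[np.ix_(pred_idx, obs_idx)] @ vinv_r)
    # profiled REML criterion up to an additive constant (comparable across
    # fits of the same data/model family only)
    ll = -float(res.fun)
    return KinshipFitResult(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        loglik=ll,
        beta=beta,
        h2=float(h2),
        ebv=pd.Series(ucap, index=np.asarray(predict_ids, dtype=object)),
    )
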