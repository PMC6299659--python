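"""Declarative cross-validation experiments for genomic selection.

Each experiment cell is a :class:`CVScenario`: a prediction model (ABLUP,
GBLUP, BRR, BLASSO, RKHS), a site scope (within one site, across sites, or
joint), one split rule (k-fold, TS/VS ratio, relatedness structure, family
or trees-per-family subsampling), an optional marker subset, and a replicate
count.  ``run_scenario`` executes the splits against a prepared
:class:`DataBundle` and emits one :class:`MetricsRecord` per replicate.

Relatedness splits follow the trial's family structure: *full-sib* keeps
families present in both training and validation; *half-sib* keeps whole
families on one side but links every validation family to training through
a shared dam; *unrelated* partitions the parents so no parent appears on
both sides.  In a diallel every parent serves as both dam and sire, so the
first parent of each family (in sorted order) is designated the dam for
split purposes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ModelError
from .lmm import ModelSpec, adjust_phenotypes, fit_reml, fit_single_kinship
from .marker_models import (
    McmcSettings,
    PriorSpec,
    fit_blasso,
    fit_brr,
    fit_rkhs,
    gaussian_kernel,
    gebv_from_effects,
)
from .metrics import MetricsRecord, accuracy, predictive_ability
from .relationship import RelationshipMatrix, g_matrix
from .simdata import GenotypeMatrix, Pedigree, PhenotypeTable, family_of

log = logging.getLogger(__name__)

MODELS = ("ablup", "gblup", "brr", "blasso", "rkhs")
SCOPES = ("within_site1", "within_site2", "cross_1to2", "cross_2to1", "joint")


@dataclass(frozen=True)
class CVScenario:
    """One experiment cell: model × scope × split rule × marker subset."""

    model: str
    scope: str = "joint"
    split: tuple = ("kfold", 10)
    marker_subset: tuple | str = "all"
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.scope not in SCOPES:
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        kind = self.split[0]
        if kind not in ("kfold", "ratio", "relatedness", "families",
                        "trees_per_family", "none"):
            raise ConfigurationError(f"unknown split rule {kind!r}")

    @property
    def label(self) -> str:
        sub = self.marker_subset
        sub_s = sub if isinstance(sub, str) else f"{sub[0]}:{sub[1]}"
        split_s = ":".join(str(x) for x in self.split)
        return f"{self.scope}|{split_s}|markers={sub_s}"


@dataclass
class SplitAssignment:
    """Disjoint training/validation id sets for one replicate."""

    replicate: int
    train_ids: np.ndarray
    valid_ids: np.ndarray

    def __post_init__(self) -> None:
        train = set(self.train_ids)
        valid = set(self.valid_ids)
        if train & valid:
            raise ModelError("training and validation sets overlap")


# ---------------------------------------------------------------------------
# Split constructors
# ---------------------------------------------------------------------------

def make_kfold(ids, k: int, seed: int) -> list[SplitAssignment]:
    """k folds, as equal as possible; every id validates exactly once."""
    ids = np.asarray(ids, dtype=object)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if len(ids) < k:
        raise ConfigurationError(f"{len(ids)} ids cannot form {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    out = []
    for f, fold in enumerate(folds):
        mask = np.zeros(len(ids), dtype=bool)
        mask[fold] = True
        out.append(SplitAssignment(f, ids[~mask], ids[mask]))
    return out


def parse_ratio(ratio: str | float) -> float:
    if isinstance(ratio, str):
        num, den = ratio.split(":")
        return float(num) / float(den)
    return float(ratio)


def make_ratio_split(ids, ratio: str | float, seed: int) -> SplitAssignment:
    """TS/VS split at ratio r:1 → training fraction r/(r+1), rounded half up."""
    ids = np.asarray(ids, dtype=object)
    if len(ids) < 2:
        raise ConfigurationError("need at least 2 ids to split")
    r = parse_ratio(ratio)
    n_train = int(math.floor(len(ids) * r / (r + 1.0) + 0.5))
    n_train = min(max(n_train, 1), len(ids) - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return SplitAssignment(0, ids[perm[:n_train]], ids[perm[n_train:]])


def _families(ped: Pedigree, ids) -> pd.Series:
    fam = family_of(ped)
    ids = np.asarray(ids, dtype=object)
    missing = [i for i in ids if i not in fam.index]
    if missing:
        raise ConfigurationError(f"{len(missing)} ids are not progeny in the pedigree")
    return fam.loc[ids]


def make_relatedness_split(
    ped: Pedigree,
    ids,
    mode: str,
    seed: int,
    vs_fraction: float = 0.1,
    vs_parent_fraction: float = 0.3,
) -> SplitAssignment:
    """TS/VS split with controlled relatedness between the sets.

    ``full_sib``: within every family with >= 2 trees, about ``vs_fraction``
    of its members validate, so families span both sets.  ``half_sib``:
    whole families are assigned to one side; every validation family shares
    its designated dam with at least one training family.  ``unrelated``:
    parents are partitioned into two disjoint groups and each family goes to
    the side owning both its parents; straddling families are discarded.
    """
    ids = np.asarray(ids, dtype=object)
    fam = _families(ped, ids)
    rng = np.random.default_rng(seed)
    if mode == "full_sib":
        valid: list = []
        for f in fam.unique():
            members = fam.index[fam == f].to_numpy()
            if len(members) < 2:
                continue
            n_vs = max(1, int(round(vs_fraction * len(members))))
            valid.extend(rng.choice(members, size=n_vs, replace=False))
        vset = set(valid)
        train = np.array([i for i in ids if i not in vset], dtype=object)
        return SplitAssignment(0, train, np.array(valid, dtype=object))

    if mode == "half_sib":
        # Whole families validate; each validation family's shared parent
        # (acting as the dam) also breeds in training, while its other parent
        # (acting as the sire) has no progeny in training at all — so the
        # strongest TS-VS tie is a half-sib pair (0.25).  Parents whose
        # families would otherwise leak into training are accumulated into a
        # "validation sire" set until the target size is met.
        parents = sorted({p for f in fam.unique() for p in f.split("x")})
        rng.shuffle(parents)
        n_target = int(round(vs_fraction * len(ids)))
        vs_sires: set[str] = set()
        assignment: tuple[np.ndarray, np.ndarray] | None = None
        for s in parents:
            vs_sires.add(s)
            ts_fams = {f for f in fam.unique()
                       if not (set(f.split("x")) & vs_sires)}
            ts_dams = {p for f in ts_fams for p in f.split("x")}
            vs_fams = set()
            for f in fam.unique():
                p1, p2 = f.split("x")
                in_s = (p1 in vs_sires) + (p2 in vs_sires)
                if in_s != 1:
                    continue  # TS family, or both parents withheld (discard)
                dam = p2 if p1 in vs_sires else p1
                if dam in ts_dams:
                    vs_fams.add(f)
            if not ts_fams or not vs_fams:
                continue
            vmask = fam.isin(vs_fams).to_numpy()
            tmask = fam.isin(ts_fams).to_numpy()
            assignment = (ids[tmask], ids[vmask])
            if int(vmask.sum()) >= n_target:
                break
        if assignment is None:
            raise ConfigurationError(
                "half-sib split impossible: cannot withhold any parent"
            )
        return SplitAssignment(0, assignment[0], assignment[1])

    if mode == "unrelated":
        parents = sorted({p for f in fam.unique() for p in f.split("x")})
        n_vs_parents = max(2, int(round(vs_parent_fraction * len(parents))))
        best: tuple[list, list] | None = None
        n_discard = 0
        for _ in range(50):  # resample the parent partition until both sides fill
            vs_parents = set(rng.choice(parents, size=n_vs_parents, replace=False))
            train_list: list = []
            valid_list: list = []
            n_discard = 0
            for f in fam.unique():
                p1, p2 = f.split("x")
                members = fam.index[fam == f].to_numpy()
                if p1 in vs_parents and p2 in vs_parents:
                    valid_list.extend(members)
                elif p1 not in vs_parents and p2 not in vs_parents:
                    train_list.extend(members)
                else:
                    n_discard += 1
            if valid_list and train_list:
                best = (train_list, valid_list)
                break
        if best is None:
            achievable = len(fam.unique()) - n_discard
            raise ConfigurationError(
                "unrelated split impossible: no sampled parent partition leaves "
                f"families on both sides (last attempt kept {achievable})"
            )
        log.info("unrelated split: %d straddling families discarded", n_discard)
        return SplitAssignment(
            0, np.array(best[0], dtype=object), np.array(best[1], dtype=object)
        )

    raise ConfigurationError(f"unknown relatedness mode {mode!r}")


def subsample_families(
    ped: Pedigree, ids, n_families: int, seed: int, vs_fraction: float = 0.1
) -> SplitAssignment:
    """TS = trees of ``n_families`` random families, minus a 10% holdout (VS)."""
    ids = np.asarray(ids, dtype=object)
    fam = _families(ped, ids)
    unique = fam.unique()
    if n_families > len(unique):
        raise ConfigurationError(
            f"requested {n_families} families, only {len(unique)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(unique, size=n_families, replace=False))
    members = fam.index[fam.isin(chosen)].to_numpy()
    n_vs = max(1, int(round(vs_fraction * len(members))))
    vs = rng.choice(members, size=n_vs, replace=False)
    vset = set(vs)
    train = np.array([i for i in members if i not in vset], dtype=object)
    return SplitAssignment(0, train, np.asarray(vs, dtype=object))


def subsample_trees(
    ped: Pedigree, ids, n_per_family: int, seed: int
) -> SplitAssignment:
    """TS = up to ``n_per_family`` random trees per family; VS = the remainder."""
    ids = np.asarray(ids, dtype=object)
    fam = _families(ped, ids)
    rng = np.random.default_rng(seed)
    train_list, valid_list = [], []
    for f in fam.unique():
        members = fam.index[fam == f].to_numpy()
        if len(members) <= n_per_family:
            if len(members) < n_per_family:
                log.info(
                    "family %s has %d trees (< %d): all to TS, none validate",
                    f, len(members), n_per_family,
                )
            train_list.extend(members)
            continue
        pick = rng.choice(members, size=n_per_family, replace=False)
        pset = set(pick)
        train_list.extend(pick)
        valid_list.extend([m for m in members if m not in pset])
    if not valid_list:
        raise ConfigurationError("no validation trees remain after subsampling")
    return SplitAssignment(
        0, np.array(train_list, dtype=object), np.array(valid_list, dtype=object)
    )


# ---------------------------------------------------------------------------
# Marker selection
# ---------------------------------------------------------------------------

def select_markers(
    yprime_train: np.ndarray,
    geno_train: GenotypeMatrix,
    mode: str,
    m: int,
    seed: int,
) -> np.ndarray:
    """Choose ``m`` marker ids: uniformly, or with the largest positive effects.

    ``largest_positive`` fits y′ = μ + x_j β_j + ε marker by marker on the
    training data and ranks by signed β̂ descending.  Monomorphic training
    markers are excluded from the ranking.
    """
    if m > geno_train.n_markers:
        raise ConfigurationError(
            f"requested {m} markers, only {geno_train.n_markers} available"
        )
    if mode == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(geno_train.n_markers, size=m, replace=False)
        return geno_train.markers[np.sort(idx)]
    if mode != "largest_positive":
        raise ConfigurationError(f"unknown marker-selection mode {mode!r}")
    X = geno_train.dosages
    y = np.asarray(yprime_train, dtype=float)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    var = (xc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (xc.T @ yc) / var
    beta[var == 0] = -np.inf  # monomorphic: excluded from ranking
    order = np.argsort(-beta, kind="stable")
    return geno_train.markers[order[:m]]


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

@dataclass
class DataBundle:
    """Matched inputs shared by every scenario of one trial and trait.

    ``yprime`` is block-adjusted, per-site standardized phenotype (one entry
    per tree), built from within-site fits so no information crosses sites;
    ``ref_ebv`` carries the reference breeding values from the full-data
    pedigree model: per-site columns (``ebv_site1``, ``ebv_site2``) and their
    mean (``ebv_mean``).
    """

    trait: str
    ped: Pedigree
    geno: GenotypeMatrix  # imputed, complete
    pheno: PhenotypeTable
    A: RelationshipMatrix
    G: RelationshipMatrix
    yprime: pd.Series
    ref_ebv: pd.DataFrame
    mcmc: McmcSettings = field(default_factory=McmcSettings.desk)
    prior: PriorSpec = field(default_factory=PriorSpec)

    def site_ids(self, site: str) -> np.ndarray:
        frame = self.pheno.frame
        return frame.loc[frame["site"] == site, "tree"].to_numpy()


def prepare_bundle(
    trait: str,
    ped: Pedigree,
    geno: GenotypeMatrix,
    pheno: PhenotypeTable,
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    mcmc: McmcSettings | None = None,
    prior: PriorSpec | None = None,
    reference_fit=None,
) -> DataBundle:
    """Assemble the shared inputs for one trait's scenario grid.

    Reference EBVs come from the full-data joint pedigree model with
    unstructured across-site additive covariance (per-site EBVs and their
    mean).  Adjusted phenotypes y′ are produced within each site from that
    site's own fit, so no information crosses sites.
    """
    if reference_fit is None:
        reference_fit = fit_reml(
            pheno, A, ModelSpec(trait=trait, kinship="A", scope="joint")
        )
    ref_ebv = reference_fit.ebv

    parts = []
    for site in pheno.sites:
        sub = PhenotypeTable(
            pheno.frame[pheno.frame["site"] == site].copy(), pheno.traits
        )
        site_fit = fit_reml(
            sub, A, ModelSpec(trait=trait, kinship="A", scope=site)
        )
        parts.append(adjust_phenotypes(sub, site_fit))
    yprime = pd.concat(parts)

    return DataBundle(
        trait=trait,
        ped=ped,
        geno=geno,
        pheno=pheno,
        A=A,
        G=G,
        yprime=yprime,
        ref_ebv=ref_ebv,
        mcmc=mcmc or McmcSettings.desk(),
        prior=prior or PriorSpec(),
    )


def _reference_column(scope: str) -> str:
    return {
        "within_site1": "ebv_site1",
        "within_site2": "ebv_site2",
        "cross_1to2": "ebv_site2",
        "cross_2to1": "ebv_site1",
        "joint": "ebv_mean",
    }[scope]


def _splits_for(
    scn: CVScenario, bundle: DataBundle, ids: np.ndarray, rep_seed: int
) -> list[SplitAssignment]:
    kind = scn.split[0]
    if kind == "kfold":
        return make_kfold(ids, int(scn.split[1]), rep_seed)
    if kind == "ratio":
        return [make_ratio_split(ids, scn.split[1], rep_seed)]
    if kind == "relatedness":
        return [make_relatedness_split(bundle.ped, ids, scn.split[1], rep_seed)]
    if kind == "families":
        return [subsample_families(bundle.ped, ids, int(scn.split[1]), rep_seed)]
    if kind == "trees_per_family":
        return [subsample_trees(bundle.ped, ids, int(scn.split[1]), rep_seed)]
    raise ConfigurationError(f"split rule {scn.split!r} not executable")


def _predict(
    scn: CVScenario,
    bundle: DataBundle,
    train_ids: np.ndarray,
    valid_ids: np.ndarray,
    rep_seed: int,
) -> pd.Series:
    """Fit the scenario's model on TS and return GEBVs for VS."""
    y_train = bundle.yprime.loc[train_ids].to_numpy()

    marker_ids = None
    if scn.marker_subset != "all":
        mode, m = scn.marker_subset
        geno_train = bundle.geno.subset(sample_ids=train_ids)
        marker_ids = select_markers(y_train, geno_train, mode, int(m), rep_seed)

    if scn.model == "ablup":
        fit = fit_single_kinship(y_train, train_ids, bundle.A, predict_ids=valid_ids)
        return fit.ebv
    if scn.model == "gblup":
        G = bundle.G
        if marker_ids is not None:
            G = g_matrix(bundle.geno.subset(marker_ids=marker_ids))
        fit = fit_single_kinship(y_train, train_ids, G, predict_ids=valid_ids)
        return fit.ebv

    geno_train = bundle.geno.subset(sample_ids=train_ids, marker_ids=marker_ids)
    mcmc = McmcSettings(
        bundle.mcmc.n_iter, bundle.mcmc.burn_in, bundle.mcmc.thin, rep_seed
    )
    if scn.model in ("brr", "blasso"):
        fitfun = fit_brr if scn.model == "brr" else fit_blasso
        eff = fitfun(y_train, geno_train, bundle.prior, mcmc)
        geno_valid = bundle.geno.subset(sample_ids=valid_ids, marker_ids=marker_ids)
        return gebv_from_effects(eff, geno_valid)
    if scn.model == "rkhs":
        both = np.concatenate([train_ids, valid_ids])
        geno_both = bundle.geno.subset(sample_ids=both, marker_ids=marker_ids)
        K = gaussian_kernel(geno_both, h=bundle.prior.rkhs_bandwidth)
        fit = fit_rkhs(y_train, K, train_ids, bundle.prior, mcmc)
        return fit.genetic_values.loc[valid_ids]
    raise ConfigurationError(f"model {scn.model!r} not executable")


def run_scenario(
    scn: CVScenario, bundle: DataBundle, strict: bool = True
) -> list[MetricsRecord]:
    """Execute all replicates of one scenario cell.

    Cross-site scopes train on one entire site and validate on the other
    (the split rule is ignored there); every other scope applies the split
    rule within its id universe.  Failed replicates are recorded and the
    scenario continues; with ``strict`` a failure rate above 20% raises.
    """
    ref_col = _reference_column(scn.scope)
    ref = bundle.ref_ebv[ref_col]
    records: list[MetricsRecord] = []
    n_failed = 0
    for rep in range(scn.n_replicates):
        rep_seed = scn.seed + rep
        try:
            if scn.scope in ("cross_1to2", "cross_2to1"):
                src = "site1" if scn.scope == "cross_1to2" else "site2"
                dst = "site2" if scn.scope == "cross_1to2" else "site1"
                splits = [
                    SplitAssignment(0, bundle.site_ids(src), bundle.site_ids(dst))
                ]
            else:
                if scn.scope == "joint":
                    ids = bundle.pheno.frame["tree"].to_numpy()
                else:
                    ids = bundle.site_ids(scn.scope.removeprefix("within_"))
                splits = _splits_for(scn, bundle, ids, rep_seed)
            gebv_parts = []
            for sp in splits:
                gebv_parts.append(
                    _predict(scn, bundle, sp.train_ids, sp.valid_ids, rep_seed)
                )
            gebv = pd.concat(gebv_parts)
            acc = accuracy(gebv, ref)
            pa = predictive_ability(gebv, bundle.yprime)
            records.append(
                MetricsRecord(
                    scenario=scn.label,
                    model=scn.model,
                    trait=bundle.trait,
                    replicate=rep,
                    accuracy=acc,
                    predictive_ability=pa,
                    n_validation=len(gebv),
                    seed=rep_seed,
                )
            )
        except Exception as exc:  # noqa: BLE001 - replicate isolation
            n_failed += 1
            log.warning("replicate %d of %s failed: %s", rep, scn.label, exc)
            records.append(
                MetricsRecord(
                    scenario=scn.label,
                    model=scn.model,
                    trait=bundle.trait,
                    replicate=rep,
                    accuracy=None,
                    predictive_ability=None,
                    n_validation=0,
                    seed=rep_seed,
                    extras={"error": str(exc)},
                )
            )
    if strict and n_failed > 0.2 * scn.n_replicates:
        raise ModelError(
            f"{n_failed}/{scn.n_replicates} replicates failed for {scn.label}"
        )
    return records
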