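"""Pedigree (A) and genomic (G) relationship matrices and their inverses.

A is built with the tabular (recursive) method from an ordered pedigree;
G follows the VanRaden dosage-centering construction
``G = (M − P)(M − P)ᵀ / (2 Σ p_i (1 − p_i))`` with ``M`` coded 0/1/2.
Two centering conventions are offered: ``vanraden`` (columns of ``P`` are
``2 p_i``, the standard form) and ``paper_literal`` (columns are
``2 (p_i − 0.5)``, the form printed in the study this pipeline emulates,
which actually centers a −1/0/1 coding and is kept only for comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._errors import ModelError, PedigreeError
from .simdata import UNKNOWN_PARENT, GenotypeMatrix, Pedigree

log = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Dense symmetric kinship-like matrix with its sample index."""

    ids: np.ndarray
    values: np.ndarray
    kind: str  # {"A", "G", "K"}
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ModelError(f"matrix shape {self.values.shape} != ({n},{n})")
        if len(set(self.ids)) != n:
            raise ModelError("duplicate ids in relationship matrix")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > 1e-8 * max(1.0, np.max(np.abs(self.values))):
            raise ModelError(f"matrix not symmetric (max asymmetry {asym:.3g})")
        self.values = 0.5 * (self.values + self.values.T)

    def subset(self, ids) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(
            np.asarray(ids, dtype=object), self.values[np.ix_(idx, idx)], self.kind
        )


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    Founders get diagonal 1; for individual *i* with parents *s*, *d*:
    ``A[i,i] = 1 + 0.5 A[s,d]`` and ``A[i,j] = 0.5 (A[j,s] + A[j,d])`` for
    every earlier individual *j*.
    """
    frame = ped.frame
    ids = ped.ids
    pos = {iid: k for k, iid in enumerate(ids)}
    for row in frame.itertuples(index=False):
        for par in (row.sire, row.dam):
            if par != UNKNOWN_PARENT and par not in pos:
                raise PedigreeError(
                    f"parent {par!r} of {row.id!r} is neither a record nor unknown"
                )
    sire_idx, dam_idx = ped.parent_indices()
    n = len(ids)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 and d < 0:
            A[i, i] = 1.0
        else:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[:i, i] = A[i, :i]
            A[i, i] = 1.0 + 0.5 * A[s, d]
    return RelationshipMatrix(ids.copy(), A, "A")


def g_matrix(
    geno: GenotypeMatrix, convention: str = "vanraden"
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from a complete dosage matrix.

    Markers are minor-allele oriented first (G is invariant to orientation
    under ``vanraden``); monomorphic markers are excluded from both the
    cross-product and the ``2 Σ p(1−p)`` denominator.
    """
    if np.isnan(geno.dosages).any():
        raise ModelError("dosage matrix contains missing entries; impute first")
    if convention not in ("vanraden", "paper_literal"):
        raise ModelError(f"unknown G convention {convention!r}")
    oriented = geno.minor_oriented()
    p = oriented.allele_freq()
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ModelError("all markers monomorphic: zero VanRaden denominator")
    if (~poly).sum():
        log.info("g_matrix: excluding %d monomorphic markers", int((~poly).sum()))
    M = oriented.dosages[:, poly]
    p = p[poly]
    if convention == "vanraden":
        centered = M - 2.0 * p
    else:
        centered = M - 2.0 * (p - 0.5)
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (centered @ centered.T) / denom
    return RelationshipMatrix(geno.samples.copy(), G, "G")


def invert_relmatrix(
    K: RelationshipMatrix, ridge: float = 0.0
) -> RelationshipMatrix:
    """Return (K + ridge·I)⁻¹ via Cholesky, with a logged 1e-6 ridge fallback."""
    n = len(K.ids)
    attempts = [ridge] if ridge > 0 else [0.0, 1e-6]
    last_exc: Exception | None = None
    for r in attempts:
        try:
            c, low = scipy.linalg.cho_factor(K.values + r * np.eye(n))
            inv = scipy.linalg.cho_solve((c, low), np.eye(n))
            if r > 0 and ridge == 0.0:
                log.warning(
                    "invert_relmatrix(%s): factorization needed fallback ridge %.1e",
                    K.kind,
                    r,
                )
            return RelationshipMatrix(K.ids.copy(), inv, K.kind, ridge=r)
        except np.linalg.LinAlgError as exc:
            last_exc = exc
            continue
    cond = np.linalg.cond(K.values)
    raise ModelError(
        f"{K.kind} matrix singular even with ridge fallback "
        f"(condition number {cond:.3g})"
    ) from last_exc
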