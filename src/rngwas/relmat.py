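"""Pedigree, genomic and combined (single-step) relationship matrices.

Implements the dense building blocks of single-step GBLUP at desk scale:
the numerator relationship matrix A by the tabular method, Henderson's
rules (with inbreeding) for A^-1, VanRaden's genomic matrix G, blupf90-style
tuning/blending of G against the genotyped-subset pedigree matrix A22, and
the single-step combined inverse

    H^-1 = A^-1 + [[0, 0], [0, G^-1 - A22^-1]]

with the genomic correction scattered onto the genotyped block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree

__all__ = [
    "pedigree_A",
    "inbreeding",
    "A_inverse",
    "vanraden_G",
    "blend_tune_G",
    "build_H_inverse",
    "RelationshipSet",
    "build_relationships",
]


def pedigree_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    For animal i with parents s and d (in topological order):
    ``A[i, i] = 1 + A[s, d] / 2`` and ``A[i, j] = (A[j, s] + A[j, d]) / 2``
    for every older j; an unknown parent contributes 0.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[:i, s]
        if d >= 0:
            row += 0.5 * A[:i, d]
        A[i, :i] = row
        A[:i, i] = row
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F = diag(A) - 1."""
    return np.diag(pedigree_A(ped)) - 1.0


def A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Inverse of A by Henderson's rules, accounting for inbreeding.

    The Mendelian-sampling variance of animal i is
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one parent known, and 1 otherwise; its
    reciprocal is added to the coefficient matrix at the usual
    animal/parent positions.
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        alpha = 1.0 / di
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= 0.5 * alpha
                Ainv[p, i] -= 0.5 * alpha
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += 0.25 * alpha
    return Ainv


def vanraden_G(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    ``G = Z Z' / (2 sum_i p_i (1 - p_i))`` with ``Z = M - P`` where M holds
    0/1/2 genotype codes (missing already imputed) and the columns of P are
    ``2 p_i`` for observed allele frequencies ``p``.

    Raises
    ------
    ValueError
        If a monomorphic marker (p in {0, 1}) is present; such markers carry
        no information and make the scaling degenerate — QC must remove them.
    """
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        bad = np.flatnonzero((p <= 0.0) | (p >= 1.0))
        raise ValueError(
            f"monomorphic markers present (indices {bad[:5].tolist()}); "
            "remove them with QC before building G"
        )
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (Z @ Z.T) / denom


def blend_tune_G(
    G: np.ndarray,
    A22: np.ndarray,
    blend_weight: float = 0.05,
    tune: bool = True,
) -> np.ndarray:
    """Tune G to the scale of A22 and blend: ``G* = (1 - w) G_t + w A22``.

    Tuning rescales G so that its mean diagonal and mean off-diagonal match
    those of A22 (solving ``A22_bar = a + b G_bar`` for intercept a and
    slope b), as the blupf90 family does by default; blending with a small
    proportion of A22 guarantees invertibility when G is rank-deficient.
    """
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 must have matching shapes")
    n = G.shape[0]
    Gt = G
    if tune and n > 1:
        off = ~np.eye(n, dtype=bool)
        gd, gn = G.diagonal().mean(), G[off].mean()
        ad, an = A22.diagonal().mean(), A22[off].mean()
        if abs(gd - gn) > 1e-12:
            b = (ad - an) / (gd - gn)
            a = ad - b * gd
            Gt = a + b * G
    Gstar = (1.0 - blend_weight) * Gt + blend_weight * A22
    # guard: blending is supposed to restore full rank
    w, _ = np.linalg.eigh(Gstar)
    if w.min() <= 1e-10 * max(w.max(), 1.0):
        raise ValueError(
            "blended G is numerically singular; increase blend_weight"
        )
    return Gstar


def build_H_inverse(
    A_inv: np.ndarray,
    A22_inv: np.ndarray,
    G_inv: np.ndarray,
    genotyped_idx: np.ndarray,
) -> np.ndarray:
    """Single-step combined inverse H^-1.

    ``H^-1 = A^-1`` plus ``G^-1 - A22^-1`` added on the genotyped block,
    where ``genotyped_idx`` gives the rows/columns of A^-1 that correspond
    (in order) to the rows of G.
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    if G_inv.shape != A22_inv.shape or len(genotyped_idx) != G_inv.shape[0]:
        raise ValueError("G_inv, A22_inv and genotyped_idx sizes disagree")
    H_inv = np.array(A_inv, dtype=float, copy=True)
    H_inv[np.ix_(genotyped_idx, genotyped_idx)] += G_inv - A22_inv
    return H_inv


@dataclass
class RelationshipSet:
    """Bundle of the matrices needed by the single-step mixed models."""

    ped: Pedigree
    A_inv: np.ndarray
    H_inv: np.ndarray
    genotyped_idx: np.ndarray | None = None
    G: np.ndarray | None = None
    A22: np.ndarray | None = None


def build_relationships(
    ped: Pedigree,
    M: np.ndarray | None = None,
    p: np.ndarray | None = None,
    genotyped_ids=None,
    blend_weight: float = 0.05,
    tune: bool = True,
) -> RelationshipSet:
    """Construct A^-1 and, when genotypes are given, the single-step H^-1.

    With no genotypes H^-1 reduces exactly to A^-1.  ``M`` holds mean-imputed
    0/1/2 codes for the genotyped animals (rows aligned with
    ``genotyped_ids``), ``p`` their observed allele frequencies.
    """
    A = pedigree_A(ped)
    F = np.diag(A) - 1.0
    A_inv = A_inverse(ped, F)
    if M is None:
        return RelationshipSet(ped, A_inv, A_inv.copy())
    if genotyped_ids is None:
        raise ValueError("genotyped_ids required when genotypes are supplied")
    gidx = ped.positions(genotyped_ids)
    A22 = A[np.ix_(gidx, gidx)]
    G = vanraden_G(M, p)
    Gstar = blend_tune_G(G, A22, blend_weight=blend_weight, tune=tune)
    G_inv = np.linalg.inv(Gstar)
    A22_inv = np.linalg.inv(A22)
    H_inv = build_H_inverse(A_inv, A22_inv, G_inv, gidx)
    return RelationshipSet(ped, A_inv, H_inv, gidx, Gstar, A22)
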