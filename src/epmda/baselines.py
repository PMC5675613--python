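"""Comparison scorers: collaborative filtering and the Katz index.

These are reconstructions from the standard textbook definitions (the
benchmark describes them only by name), sharing the diffusion scorer's
contract so they plug into the same cross-validation harness: miRNAs
play the role of users, diseases of items, and the known association
matrix is the (binary) rating matrix.
"""

from __future__ import annotations

import logging

import numpy as np

from .diffusion import ScoreMatrix  # noqa: F401  (re-exported for CLI symmetry)

logger = logging.getLogger(__name__)

__all__ = [
    "user_based_cf",
    "item_based_cf",
    "neighbor_based_cf",
    "heterogeneous_network",
    "katz_scores",
    "make_user_cf_scorer",
    "make_item_cf_scorer",
    "make_neighbor_cf_scorer",
    "make_katz_scorer",
]


def _as_array(x) -> np.ndarray:
    return x.S if hasattr(x, "S") else (x.A if hasattr(x, "A") else np.asarray(x, dtype=float))


def user_based_cf(A, SM_mir) -> np.ndarray:
    """Similarity-weighted average over other miRNAs' associations.

    score(i, j) = sum_{k != i} SM_mir(i,k) A(k,j) / sum_{k != i} |SM_mir(i,k)|,
    with 0/0 -> 0.
    """
    A = _as_array(A)
    S = _as_array(SM_mir).copy()
    if S.shape != (A.shape[0], A.shape[0]):
        raise ValueError("miRNA similarity shape does not match association rows")
    np.fill_diagonal(S, 0.0)
    num = S @ A
    den = np.abs(S).sum(axis=1)
    return np.where(den[:, None] != 0.0, num / np.where(den == 0.0, 1.0, den)[:, None], 0.0)


def item_based_cf(A, SM_dis) -> np.ndarray:
    """Mirror of user_based_cf over disease similarity.

    score(i, j) = sum_{l != j} A(i,l) SM_dis(l,j) / sum_{l != j} |SM_dis(l,j)|.
    """
    A = _as_array(A)
    S = _as_array(SM_dis).copy()
    if S.shape != (A.shape[1], A.shape[1]):
        raise ValueError("disease similarity shape does not match association columns")
    np.fill_diagonal(S, 0.0)
    num = A @ S
    den = np.abs(S).sum(axis=0)
    return np.where(den[None, :] != 0.0, num / np.where(den == 0.0, 1.0, den)[None, :], 0.0)


def neighbor_based_cf(A, SM_mir, SM_dis, lam: float = 0.5) -> np.ndarray:
    """Convex blend of the user- and item-based filters."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * user_based_cf(A, SM_mir) + (1.0 - lam) * item_based_cf(A, SM_dis)


def heterogeneous_network(A, SM_mir, SM_dis) -> np.ndarray:
    """Symmetric block matrix [[SM_mir, A], [A.T, SM_dis]] (miRNA block first)."""
    A = _as_array(A)
    Sm = _as_array(SM_mir)
    Sd = _as_array(SM_dis)
    return np.block([[Sm, A], [A.T, Sd]])


def katz_scores(
    A,
    SM_mir,
    SM_dis,
    katz_beta: float = 0.01,
    max_length: int = 4,
    include_direct: bool = True,
) -> np.ndarray:
    """Damped walk counts on the heterogeneous miRNA/disease network.

    Sums beta**l * H**l for walk lengths l = 2 .. max_length and takes
    the miRNA x disease block; ``include_direct`` adds the length-1
    (direct edge) term beta * A.
    """
    if katz_beta <= 0:
        raise ValueError("katz_beta must be positive")
    if max_length < 2:
        raise ValueError("max_length must be >= 2")
    A = _as_array(A)
    n_m = A.shape[0]
    H = heterogeneous_network(A, SM_mir, SM_dis)
    radius = float(np.max(np.abs(np.linalg.eigvalsh(H)))) if H.size else 0.0
    if radius > 0 and katz_beta >= 1.0 / radius:
        logger.warning(
            "katz_beta=%g is at or above 1/spectral-radius (%g); walk series "
            "would diverge if extended", katz_beta, 1.0 / radius,
        )
    total = np.zeros_like(H)
    power = H.copy()  # H^1
    for length in range(2, max_length + 1):
        power = power @ H
        total += katz_beta**length * power
        if not np.isfinite(total).all():
            raise ArithmeticError(
                f"Katz walk sum overflowed at length {length}; use a smaller katz_beta"
            )
    block = total[:n_m, n_m:]
    if include_direct:
        block = block + katz_beta * A
    return block


def make_user_cf_scorer(SM_mir):
    def scorer(A_train: np.ndarray) -> np.ndarray:
        return user_based_cf(A_train, SM_mir)

    return scorer


def make_item_cf_scorer(SM_dis):
    def scorer(A_train: np.ndarray) -> np.ndarray:
        return item_based_cf(A_train, SM_dis)

    return scorer


def make_neighbor_cf_scorer(SM_mir, SM_dis, lam: float = 0.5):
    def scorer(A_train: np.ndarray) -> np.ndarray:
        return neighbor_based_cf(A_train, SM_mir, SM_dis, lam)

    return scorer


def make_katz_scorer(SM_mir, SM_dis, katz_beta: float = 0.01, max_length: int = 4,
                     include_direct: bool = True):
    def scorer(A_train: np.ndarray) -> np.ndarray:
        return katz_scores(A_train, SM_mir, SM_dis, katz_beta, max_length, include_direct)

    return scorer
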