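"""Two-way diffusion scorer on the bipartite association network.

The known miRNA-disease association network (binary matrix A, rows =
miRNAs) is first re-weighted twice: once through disease semantic
similarity (A_d = A @ SM_dis) and once through miRNA expression
similarity (A_m = SM_mir @ A).  Resource then flows in two steps over
each weighted copy:

step 1 (resource)
    Each weighted edge's share of its column (resp. row) mass carries a
    copy of the raw association pattern of the opposite side, producing
    miRNA-miRNA and disease-disease resource matrices.  The two weighted
    streams are blended convexly with damping coefficients alpha (miRNA
    side) and beta (disease side).
step 2 (feedback)
    The blended resource matrices are pushed back through the same edge
    shares, giving an n_m x n_d feedback score from the miRNA side and
    an n_d x n_m one from the disease side.
step 3 (combination)
    The final score matrix is the average of the miRNA-side feedback
    and the transposed disease-side feedback.

Edges incident to isolated nodes (zero row or column mass, as happens
when cross-validation removes a node's last association) contribute
zero flow rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disease_similarity import DiseaseSimilarityMatrix, read_disease_dags, build_disease_similarity
from .io import AssociationMatrix, RunConfig, build_association_matrix, read_association_table
from .mirna_similarity import (
    MicroRNASimilarityMatrix,
    build_mirna_similarity,
    read_expression_profiles,
)

__all__ = [
    "WeightedNetworks",
    "ScoreMatrix",
    "build_weighted_networks",
    "diffusion_shares",
    "two_way_diffusion",
    "epmda_scores",
    "make_epmda_scorer",
    "predict",
]


@dataclass
class WeightedNetworks:
    """Disease- and miRNA-similarity-weighted copies of the association network."""

    A_d: np.ndarray
    A_m: np.ndarray

    def __post_init__(self) -> None:
        self.A_d = np.asarray(self.A_d, dtype=float)
        self.A_m = np.asarray(self.A_m, dtype=float)
        if self.A_d.shape != self.A_m.shape:
            raise ValueError("weighted networks must share the association shape")


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores, rows = miRNAs, columns = diseases."""

    SS: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.SS = np.asarray(self.SS, dtype=float)
        if self.SS.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("score shape does not match id lists")


def build_weighted_networks(
    A: np.ndarray | AssociationMatrix,
    SM_dis: np.ndarray | DiseaseSimilarityMatrix,
    SM_mir: np.ndarray | MicroRNASimilarityMatrix,
) -> WeightedNetworks:
    """A_d = A @ SM_dis (disease-side weighting), A_m = SM_mir @ A.

    With identity similarity matrices both weighted copies equal A.
    """
    A = A.A if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    Sd = SM_dis.S if isinstance(SM_dis, DiseaseSimilarityMatrix) else np.asarray(SM_dis, dtype=float)
    Sm = SM_mir.S if isinstance(SM_mir, MicroRNASimilarityMatrix) else np.asarray(SM_mir, dtype=float)
    n_m, n_d = A.shape
    if Sd.shape != (n_d, n_d):
        raise ValueError(f"disease similarity must be {n_d}x{n_d}, got {Sd.shape}")
    if Sm.shape != (n_m, n_m):
        raise ValueError(f"miRNA similarity must be {n_m}x{n_m}, got {Sm.shape}")
    return WeightedNetworks(A_d=A @ Sd, A_m=Sm @ A)


def diffusion_shares(A_w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column shares W and row shares M of a weighted network, with 0/0 -> 0."""
    A_w = np.asarray(A_w, dtype=float)
    if not np.isfinite(A_w).all():
        raise ValueError("weighted network contains non-finite entries")
    col = A_w.sum(axis=0)
    row = A_w.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(col != 0.0, A_w / np.where(col == 0.0, 1.0, col), 0.0)
        M = np.where(row[:, None] != 0.0, A_w / np.where(row == 0.0, 1.0, row)[:, None], 0.0)
    return W, M


def two_way_diffusion(
    A: np.ndarray | AssociationMatrix,
    nets: WeightedNetworks,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> np.ndarray:
    """Run the three-step diffusion and return the n_m x n_d score matrix.

    alpha blends the disease-weighted and miRNA-weighted streams on the
    miRNA side, beta on the disease side; both 0.5 by default.  The
    diffusion is exactly two flow steps (resource + feedback), not an
    iterated walk.
    """
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("alpha and beta must lie in [0, 1]")
    A = A.A if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)

    W_d, M_d = diffusion_shares(nets.A_d)
    W_m, M_m = diffusion_shares(nets.A_m)

    # step 1: resource matrices (miRNA x miRNA and disease x disease)
    S1_mir = alpha * (W_d @ A.T) + (1.0 - alpha) * (W_m @ A.T)
    S1_dis = beta * (M_d.T @ A) + (1.0 - beta) * (M_m.T @ A)
    if not (np.isfinite(S1_mir).all() and np.isfinite(S1_dis).all()):
        raise ArithmeticError("non-finite values in diffusion step 1 (resource)")

    # step 2: feedback through the same edge shares
    S2_mir = alpha * (W_d @ S1_dis) + (1.0 - alpha) * (W_m @ S1_dis)
    S2_dis = beta * (M_d.T @ S1_mir) + (1.0 - beta) * (M_m.T @ S1_mir)
    if not (np.isfinite(S2_mir).all() and np.isfinite(S2_dis).all()):
        raise ArithmeticError("non-finite values in diffusion step 2 (feedback)")

    # step 3: average the two feedback directions
    return (S2_mir + S2_dis.T) / 2.0


def epmda_scores(
    A: np.ndarray,
    SM_mir: np.ndarray | MicroRNASimilarityMatrix,
    SM_dis: np.ndarray | DiseaseSimilarityMatrix,
    alpha: float = 0.5,
    beta: float = 0.5,
) -> np.ndarray:
    """Weighted networks + two-way diffusion in one call (scorer contract)."""
    nets = build_weighted_networks(A, SM_dis, SM_mir)
    return two_way_diffusion(A, nets, alpha=alpha, beta=beta)


def make_epmda_scorer(
    SM_mir: np.ndarray | MicroRNASimilarityMatrix,
    SM_dis: np.ndarray | DiseaseSimilarityMatrix,
    alpha: float = 0.5,
    beta: float = 0.5,
):
    """Bind similarities and damping into an ``A_train -> scores`` callable."""

    def scorer(A_train: np.ndarray) -> np.ndarray:
        return epmda_scores(A_train, SM_mir, SM_dis, alpha=alpha, beta=beta)

    return scorer


def predict(
    association_path,
    expression_path,
    dag_path,
    config: RunConfig | None = None,
) -> ScoreMatrix:
    """End-to-end pipeline from the three input files to a labelled score matrix.

    The association file fixes the miRNA and disease universes (order of
    first appearance); miRNAs without expression rows and diseases
    without DAGs are handled by the respective mean-imputation rules.
    """
    config = config or RunConfig()
    amat = build_association_matrix(read_association_table(association_path))
    profiles = read_expression_profiles(expression_path)
    sm_mir = build_mirna_similarity(
        profiles,
        amat.mirna_ids,
        clip_negative=config.clip_negative_similarity,
        treat_constant_as_missing=config.treat_constant_as_missing,
    )
    dags = read_disease_dags(dag_path)
    sm_dis = build_disease_similarity(dags, amat.disease_ids, config.delta)
    SS = epmda_scores(amat.A, sm_mir, sm_dis, alpha=config.alpha, beta=config.beta)
    return ScoreMatrix(SS=SS, mirna_ids=amat.mirna_ids, disease_ids=amat.disease_ids)
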