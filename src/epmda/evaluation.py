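"""Cross-validation harness, ROC/AUC and candidate ranking.

Every evaluated scorer obeys the same contract: it receives a training
association matrix (a copy of the full binary matrix with the held-out
pairs zeroed) and returns a real score matrix of the same shape.  Held
out pairs are always ranked against the *candidate* pool — the pairs
that are zero in the full known-association matrix — never against
other training positives; this is the convention shared by the link
prediction models the method is compared with.

The AUC of a round is the Mann-Whitney concordance of the held-out
score(s) against the candidate scores (ties count 0.5); the overall
cross-validation AUC averages the rounds.  Leave-one-out is the special
case of one held-out pair per round, and k-fold with k equal to the
number of known pairs reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "RocResult",
    "CvResult",
    "LoocvResult",
    "roc_auc",
    "loocv",
    "kfold_cv",
    "rank_disease_candidates",
]

Scorer = Callable[[np.ndarray], np.ndarray]


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class LoocvResult:
    auc: float
    roc: RocResult
    rank_table: pd.DataFrame


@dataclass
class CvResult:
    per_repetition_auc: list[float]
    mean_auc: float
    sd_auc: float
    folds: int
    repetitions: int
    seed: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC sweep and trapezoidal AUC.

    The AUC equals the pairwise-concordance statistic
    (#{pos > neg} + 0.5 * #{pos = neg}) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal-length")
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all() or classes.size != 2:
        raise ValueError("labels must contain both classes 0 and 1")
    fpr, tpr, thr = roc_curve(labels, scores)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(np.trapezoid(tpr, fpr)))


def _concordance_fractions(
    held_scores: np.ndarray, candidate_scores_sorted: np.ndarray
) -> np.ndarray:
    """Fraction of candidates strictly below each held-out score (+0.5 per tie)."""
    n = candidate_scores_sorted.size
    lo = np.searchsorted(candidate_scores_sorted, held_scores, side="left")
    hi = np.searchsorted(candidate_scores_sorted, held_scores, side="right")
    return (lo + 0.5 * (hi - lo)) / n


def _check_candidates(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.argwhere(A == 1)
    neg = np.argwhere(A == 0)
    if len(pos) < 2:
        raise ValueError("need at least 2 known associations")
    if len(neg) == 0:
        raise ValueError("no candidate (unknown) pairs to rank against")
    return pos, neg


def loocv(
    A: np.ndarray,
    scorer: Scorer,
    mirna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> LoocvResult:
    """Leave each known association out in turn and rank it among candidates.

    Returns the mean per-round concordance as the AUC, a pooled ROC
    curve over all rounds (held-out pairs as positives, that round's
    candidate scores as negatives), and a per-holdout rank table.
    """
    A = np.asarray(A, dtype=float)
    pos, neg = _check_candidates(A)
    neg_idx = (neg[:, 0], neg[:, 1])
    n_cand = len(neg)

    fractions = np.empty(len(pos))
    held_scores = np.empty(len(pos))
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    rows = []
    for k, (i, j) in enumerate(pos):
        A_train = A.copy()
        A_train[i, j] = 0.0
        try:
            S = np.asarray(scorer(A_train), dtype=float)
        except Exception as exc:  # surface which holdout failed
            raise RuntimeError(f"scorer failed in LOOCV round {k} (pair {i},{j})") from exc
        cand = np.sort(S[neg_idx])
        s = S[i, j]
        frac = _concordance_fractions(np.array([s]), cand)[0]
        fractions[k] = frac
        held_scores[k] = s
        pooled_scores.append(np.concatenate(([s], S[neg_idx])))
        pooled_labels.append(np.concatenate(([1], np.zeros(n_cand, dtype=int))))
        rows.append(
            {
                "mirna": mirna_ids[i] if mirna_ids is not None else str(i),
                "disease": disease_ids[j] if disease_ids is not None else str(j),
                "score": s,
                "concordance": frac,
                "rank": int(round((1.0 - frac) * n_cand)) + 1,
                "n_candidates": n_cand,
            }
        )
    roc = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return LoocvResult(
        auc=float(fractions.mean()),
        roc=roc,
        rank_table=pd.DataFrame(rows),
    )


def kfold_cv(
    A: np.ndarray,
    scorer: Scorer,
    folds: int = 5,
    repetitions: int = 20,
    seed: int = 0,
) -> CvResult:
    """Repeated k-fold cross-validation over the known associations.

    Per repetition the known pairs are shuffled with a repetition
    specific seed (base seed + repetition index) and split into folds
    differing in size by at most one; each fold is zeroed in the
    training matrix, scored, and its pairs pooled against the candidate
    pool.  The repetition AUC averages the fold AUCs.
    """
    A = np.asarray(A, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    pos, neg = _check_candidates(A)
    if len(pos) < folds:
        raise ValueError(f"{len(pos)} known associations cannot fill {folds} folds")
    neg_idx = (neg[:, 0], neg[:, 1])

    per_rep = []
    for rep in range(repetitions):
        rng = np.random.default_rng(seed + rep)
        order = rng.permutation(len(pos))
        fold_aucs = []
        for fold_ids in np.array_split(order, folds):
            A_train = A.copy()
            A_train[pos[fold_ids, 0], pos[fold_ids, 1]] = 0.0
            try:
                S = np.asarray(scorer(A_train), dtype=float)
            except Exception as exc:
                raise RuntimeError(f"scorer failed in repetition {rep}") from exc
            cand = np.sort(S[neg_idx])
            fracs = _concordance_fractions(S[pos[fold_ids, 0], pos[fold_ids, 1]], cand)
            fold_aucs.append(float(fracs.mean()))
        per_rep.append(float(np.mean(fold_aucs)))

    mean = float(np.mean(per_rep))
    sd = float(np.std(per_rep, ddof=1)) if repetitions > 1 else 0.0
    return CvResult(
        per_repetition_auc=per_rep,
        mean_auc=mean,
        sd_auc=sd,
        folds=folds,
        repetitions=repetitions,
        seed=seed,
    )


def rank_disease_candidates(
    score,
    disease_id: str,
    top_k: int | None = None,
    exclude_known: bool = False,
    A_known: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank miRNAs for one disease by score, descending, ties by input order.

    With ``exclude_known`` the miRNAs already associated in ``A_known``
    are dropped before ranking (case-study mode: train on everything,
    rank the remaining candidates).
    """
    if disease_id not in score.disease_ids:
        raise KeyError(f"unknown disease id {disease_id!r}")
    j = score.disease_ids.index(disease_id)
    col = score.SS[:, j]
    keep = np.ones(len(col), dtype=bool)
    if exclude_known:
        if A_known is None:
            raise ValueError("exclude_known requires the known association matrix")
        keep = np.asarray(A_known, dtype=float)[:, j] == 0.0
    idx = np.where(keep)[0]
    order = idx[np.argsort(-col[idx], kind="stable")]
    if top_k is not None:
        order = order[:top_k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "mirna": [score.mirna_ids[i] for i in order],
            "score": col[order],
        }
    )
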