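"""miRNA expression similarity.

Each miRNA is a vector of expression levels across human tissues and
cell lines; similarity between two miRNAs is the Pearson correlation of
their profiles.  Profiles are not available for every miRNA in the
association universe: any pair involving a profile-less miRNA receives
the arithmetic mean of all computable off-diagonal pair similarities
(a single shared value), and those entries are flagged in an imputation
mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionProfileMatrix",
    "MicroRNASimilarityMatrix",
    "read_expression_profiles",
    "write_expression_profiles",
    "pearson_similarity",
    "build_mirna_similarity",
]


@dataclass
class ExpressionProfileMatrix:
    """Real miRNA x tissue matrix; rows exist only for profiled miRNAs."""

    values: np.ndarray
    mirna_ids: list[str]
    tissue_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirna_ids), len(self.tissue_ids)):
            raise ValueError("profile shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("expression profiles contain non-finite values")
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids in expression profiles")


@dataclass
class MicroRNASimilarityMatrix:
    """Symmetric unit-diagonal similarity with an imputed-entry mask."""

    S: np.ndarray
    mirna_ids: list[str]
    imputed: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        n = len(self.mirna_ids)
        if self.S.shape != (n, n) or self.imputed.shape != (n, n):
            raise ValueError("similarity shape does not match id list")


def read_expression_profiles(path: str | Path) -> ExpressionProfileMatrix:
    """Read a TSV profile file: header row = tissue ids, first column = miRNA id."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no tissue columns found")
    return ExpressionProfileMatrix(
        values=df.to_numpy(dtype=float),
        mirna_ids=[str(i) for i in df.index],
        tissue_ids=[str(c) for c in df.columns],
    )


def write_expression_profiles(profiles: ExpressionProfileMatrix, path: str | Path) -> None:
    df = pd.DataFrame(profiles.values, index=profiles.mirna_ids, columns=profiles.tissue_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="mirna_id")


def pearson_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Centered Pearson correlation of two equal-length profiles.

    Raises on vectors shorter than 2 or with zero variance, where the
    correlation is undefined; the caller decides the policy for such
    profiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("profiles must have length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("undefined correlation: zero-variance profile")
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


def build_mirna_similarity(
    profiles: ExpressionProfileMatrix,
    universe: Sequence[str],
    *,
    clip_negative: bool = False,
    treat_constant_as_missing: bool = False,
) -> MicroRNASimilarityMatrix:
    """Assemble the full miRNA similarity matrix over ``universe``.

    Pairs with both profiles present get their Pearson correlation; any
    pair touching a profile-less miRNA gets the mean of all computable
    off-diagonal values.  The diagonal is 1 and the ``imputed`` mask
    marks exactly the mean-filled entries.

    Parameters
    ----------
    clip_negative
        Zero out negative correlations (applied before the imputation
        mean is taken, so the mean is consistent with the stored values).
    treat_constant_as_missing
        Route zero-variance profiles through the missing-profile rule
        instead of raising.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty miRNA universe")
    if len(set(universe)) != len(universe):
        raise ValueError("duplicate ids in miRNA universe")
    row_of = {m: i for i, m in enumerate(profiles.mirna_ids)}
    extra = set(profiles.mirna_ids) - set(universe)
    if extra:
        logger.info("ignoring %d profiled miRNAs outside the universe", len(extra))

    n = len(universe)
    avail = np.array([m in row_of for m in universe])
    if avail.any():
        sub = profiles.values[[row_of[m] for m in np.array(universe)[avail]]]
        sd = sub.std(axis=1)
        if (sd == 0).any():
            bad = [m for m, s in zip(np.array(universe)[avail], sd) if s == 0]
            if treat_constant_as_missing:
                logger.warning("treating constant profiles as missing: %s", bad)
                keep = sd > 0
                names = [m for m, k in zip(np.array(universe)[avail], keep) if k]
                avail = np.array([m in set(names) for m in universe])
                sub = profiles.values[[row_of[m] for m in names]]
            else:
                raise ValueError(f"zero-variance expression profile for {bad[0]}")

    n_avail = int(avail.sum())
    n_missing = n - n_avail
    S = np.empty((n, n))
    if n_avail >= 2:
        C = np.eye(n_avail)
        for a in range(n_avail):
            for b in range(a + 1, n_avail):
                C[a, b] = C[b, a] = pearson_similarity(sub[a], sub[b])
        if clip_negative:
            C = np.maximum(C, 0.0)
    elif n_avail == 1:
        C = np.ones((1, 1))
    else:
        C = np.zeros((0, 0))

    if n_missing > 0:
        iu, ju = np.triu_indices(n_avail, k=1)
        if iu.size == 0:
            raise ValueError(
                "cannot impute missing-profile similarities: "
                "no computable miRNA pair exists"
            )
        mean_sim = float(C[iu, ju].mean())
        S[:] = mean_sim

    idx = np.where(avail)[0]
    S[np.ix_(idx, idx)] = C
    np.fill_diagonal(S, 1.0)

    imputed = np.zeros((n, n), dtype=bool)
    if n_missing > 0:
        miss = ~avail
        imputed[miss, :] = True
        imputed[:, miss] = True
        np.fill_diagonal(imputed, False)
    return MicroRNASimilarityMatrix(S=S, mirna_ids=universe, imputed=imputed)
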