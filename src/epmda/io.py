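"""Readers, writers and core indexed containers.

All on-disk artifacts are plain text: association lists are two-column
TSV/CSV files, matrices are labelled TSV, disease DAGs are three-column
edge lists.  Lines starting with ``#`` are comments everywhere.  Row and
column orderings follow first appearance in the source file so that the
same input always produces the same index maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "AssociationMatrix",
    "RunConfig",
    "read_association_table",
    "write_association_table",
    "build_association_matrix",
    "write_score_matrix",
    "read_matrix",
    "write_labeled_matrix",
    "load_config",
]


@dataclass(frozen=True)
class AssociationTable:
    """Deduplicated list of (mirna_id, disease_id) pairs in file order."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.records)) != len(self.records):
            raise ValueError("association table contains duplicate pairs")
        for m, d in self.records:
            if not m or not d or m != m.strip() or d != d.strip():
                raise ValueError(f"malformed record ({m!r}, {d!r})")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AssociationMatrix:
    """Binary adjacency of the known association network.

    Rows are miRNAs, columns are diseases; ``A[i, j] == 1`` iff the pair
    (mirna_ids[i], disease_ids[j]) is a known association.
    """

    A: np.ndarray
    mirna_ids: list[str]
    disease_ids: list[str]
    mirna_index: dict[str, int] = field(init=False)
    disease_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.mirna_index = {m: i for i, m in enumerate(self.mirna_ids)}
        self.disease_index = {d: j for j, d in enumerate(self.disease_ids)}
        if len(self.mirna_index) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        if len(self.disease_index) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)


@dataclass
class RunConfig:
    """Run-wide parameters.

    alpha, beta
        Damping coefficients balancing the disease-weighted and the
        miRNA-weighted network streams in the two-way diffusion; both
        default to 0.5.
    delta
        Semantic-contribution decay factor per DAG level, default 0.5.
    clip_negative_similarity
        Replace negative expression correlations by 0 before diffusion.
    lambda_neighbor
        Mixing weight of the neighbor-based collaborative filter.
    katz_beta, katz_max_length, katz_include_direct
        Damping, walk-length cap and direct-edge term of the Katz index.
    """

    alpha: float = 0.5
    beta: float = 0.5
    delta: float = 0.5
    clip_negative_similarity: bool = False
    treat_constant_as_missing: bool = False
    lambda_neighbor: float = 0.5
    katz_beta: float = 0.01
    katz_max_length: int = 4
    katz_include_direct: bool = True
    seed: int = 0
    cv_folds: int = 5
    cv_repetitions: int = 20

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lambda_neighbor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")
        if self.katz_beta <= 0:
            raise ValueError("katz_beta must be positive")
        if self.katz_max_length < 2:
            raise ValueError("katz_max_length must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repetitions < 1:
            raise ValueError("cv_repetitions must be >= 1")


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Build a RunConfig from a flat key-value YAML file plus overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} is not a flat key-value mapping")
        known = {f.name for f in fields(RunConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _detect_separator(line: str) -> str:
    return "\t" if "\t" in line else ","


def _iter_data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_association_table(path: str | Path) -> AssociationTable:
    """Read a two-column miRNA/disease pair list, dropping exact repeats.

    The separator (tab or comma) is auto-detected from the first data
    line.  Duplicate pairs are removed with a log message; the surviving
    order is first appearance.
    """
    sep: str | None = None
    seen: dict[tuple[str, str], None] = {}
    n_dup = 0
    for lineno, line in _iter_data_lines(path):
        if sep is None:
            sep = _detect_separator(line)
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(
                f"{path}: line {lineno}: expected at least two "
                f"non-empty {'tab' if sep == chr(9) else 'comma'}-separated fields"
            )
        pair = (parts[0], parts[1])
        if pair in seen:
            n_dup += 1
        else:
            seen[pair] = None
    if not seen:
        raise ValueError(f"{path}: no association records found")
    if n_dup:
        logger.info("%s: removed %d repetitive records", path, n_dup)
    return AssociationTable(records=tuple(seen))


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#mirna_id\tdisease_id\n")
        for m, d in table.records:
            fh.write(f"{m}\t{d}\n")


def build_association_matrix(table: AssociationTable) -> AssociationMatrix:
    """Index the pair list into a binary miRNA x disease matrix.

    Ids are ordered by first appearance in the table.
    """
    if len(table) == 0:
        raise ValueError("empty association table")
    mirna_ids: list[str] = []
    disease_ids: list[str] = []
    mi: dict[str, int] = {}
    di: dict[str, int] = {}
    for m, d in table.records:
        if m not in mi:
            mi[m] = len(mirna_ids)
            mirna_ids.append(m)
        if d not in di:
            di[d] = len(disease_ids)
            disease_ids.append(d)
    A = np.zeros((len(mirna_ids), len(disease_ids)))
    for m, d in table.records:
        A[mi[m], di[d]] = 1.0
    return AssociationMatrix(A=A, mirna_ids=mirna_ids, disease_ids=disease_ids)


def write_labeled_matrix(
    values: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
    path: str | Path,
) -> None:
    """Write a labelled real matrix as TSV (col ids header, row ids first column)."""
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite entries")
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a labelled TSV matrix back as (values, row_ids, col_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_score_matrix(score, path: str | Path) -> None:
    """Write a ScoreMatrix (anything with SS / mirna_ids / disease_ids) to TSV."""
    write_labeled_matrix(score.SS, score.mirna_ids, score.disease_ids, path)
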