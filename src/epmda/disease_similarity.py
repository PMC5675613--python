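"""Disease semantic similarity on MeSH-style DAGs.

A disease is described by a directed acyclic graph: its own descriptor
term plus all ancestor terms, with child -> parent edges.  Each term t
contributes to the disease's semantics with a weight decayed by a factor
delta per level: the disease term contributes 1, and every other term
contributes delta raised to the minimum number of descending edges from
the term down to the disease.  Two diseases are similar to the extent
their DAGs share terms, relative to the total contribution mass of both
DAGs, which yields values in [0, 1] with self-similarity exactly 1.

Diseases that lack a DAG (real MeSH coverage is incomplete) get the mean
of all computable off-diagonal disease-pair similarities, mirroring the
missing-profile rule on the miRNA side; those entries are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DiseaseDAG",
    "SemanticContribution",
    "DiseaseSimilarityMatrix",
    "read_disease_dags",
    "write_disease_dags",
    "semantic_contribution",
    "semantic_similarity",
    "build_disease_similarity",
]


@dataclass
class DiseaseDAG:
    """One disease's term DAG: its descriptor term plus all ancestors.

    ``edges`` are (child, parent) pairs; ``term`` is the disease's own
    descriptor (defaults to the disease id) and is the sink of
    contribution flow (no children inside the DAG).  Distinct disease
    ids may share one descriptor, in which case their DAGs coincide.
    """

    disease_id: str
    terms: frozenset[str]
    edges: frozenset[tuple[str, str]]
    term: str | None = None

    def __post_init__(self) -> None:
        self.terms = frozenset(self.terms)
        self.edges = frozenset(self.edges)
        if self.term is None:
            self.term = self.disease_id
        for c, p in self.edges:
            if c not in self.terms or p not in self.terms:
                raise ValueError(
                    f"DAG for {self.disease_id}: edge ({c},{p}) outside term set"
                )
        if self.term not in self.terms:
            raise ValueError(f"DAG for {self.disease_id} lacks the disease's own term")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"cycle detected in DAG for {self.disease_id}")
        if g.in_degree(self.term) != 0:
            raise ValueError(
                f"DAG for {self.disease_id}: disease term has children; "
                "it must be the sink of contribution flow"
            )

    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph over the term set."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    @property
    def root_terms(self) -> frozenset[str]:
        g = self.graph()
        return frozenset(t for t in self.terms if g.out_degree(t) == 0)


@dataclass
class SemanticContribution:
    disease_id: str
    contrib: dict[str, float]


@dataclass
class DiseaseSimilarityMatrix:
    S: np.ndarray
    disease_ids: list[str]
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.disease_ids)
        if self.imputed is None:
            self.imputed = np.zeros((n, n), dtype=bool)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.S.shape != (n, n) or self.imputed.shape != (n, n):
            raise ValueError("similarity shape does not match id list")


def read_disease_dags(path: str | Path) -> list[DiseaseDAG]:
    """Read a TSV edge list with columns disease_id, child_term, parent_term."""
    edges_by_disease: dict[str, set[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 3 or not all(parts[:3]):
                raise ValueError(
                    f"{path}: line {lineno}: expected three tab-separated fields "
                    "(disease_id, child_term, parent_term)"
                )
            edges_by_disease.setdefault(parts[0], set()).add((parts[1], parts[2]))
    dags = []
    for disease_id, edges in edges_by_disease.items():
        terms = {disease_id} | {t for e in edges for t in e}
        dags.append(DiseaseDAG(disease_id=disease_id, terms=frozenset(terms), edges=frozenset(edges)))
    return dags


def write_disease_dags(dags: Iterable[DiseaseDAG], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#disease_id\tchild_term\tparent_term\n")
        for dag in dags:
            for child, parent in sorted(dag.edges):
                fh.write(f"{dag.disease_id}\t{child}\t{parent}\n")


def semantic_contribution(dag: DiseaseDAG, delta: float) -> SemanticContribution:
    """Decayed contribution of every DAG term to its disease.

    The disease term gets 1; a term at minimum descending distance k
    gets delta**k.  Computed by breadth-first search up the child ->
    parent edges, which is the dynamic-programming form of taking, at
    each term, the maximum of delta times any child's contribution.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    g = dag.graph()
    dist = nx.single_source_shortest_path_length(g, dag.term)
    missing = dag.terms - set(dist)
    if missing:
        raise ValueError(
            f"DAG for {dag.disease_id}: terms {sorted(missing)} have no "
            "descending path to the disease term"
        )
    return SemanticContribution(
        disease_id=dag.disease_id,
        contrib={t: delta**k for t, k in dist.items()},
    )


def semantic_similarity(c_i: SemanticContribution, c_j: SemanticContribution) -> float:
    """Shared-contribution ratio of two diseases; 0 for disjoint DAGs, 1 for identical."""
    shared = set(c_i.contrib) & set(c_j.contrib)
    if not shared:
        return 0.0
    num = sum(c_i.contrib[t] + c_j.contrib[t] for t in shared)
    den = sum(c_i.contrib.values()) + sum(c_j.contrib.values())
    return num / den


def build_disease_similarity(
    dags: Sequence[DiseaseDAG],
    universe: Sequence[str],
    delta: float,
) -> DiseaseSimilarityMatrix:
    """Pairwise semantic similarity over ``universe``, with the mean rule
    for diseases lacking a DAG and the diagonal forced to 1."""
    universe = list(universe)
    if not universe:
        raise ValueError("empty disease universe")
    seen: dict[str, DiseaseDAG] = {}
    for dag in dags:
        if dag.disease_id in seen:
            raise ValueError(f"duplicate DAG for disease {dag.disease_id}")
        seen[dag.disease_id] = dag

    contribs = {
        d: semantic_contribution(seen[d], delta) for d in universe if d in seen
    }
    have = [d in contribs for d in universe]
    n = len(universe)
    idx = [i for i, h in enumerate(have) if h]

    block = np.ones((len(idx), len(idx)))
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            s = semantic_similarity(
                contribs[universe[idx[a]]], contribs[universe[idx[b]]]
            )
            block[a, b] = block[b, a] = s

    S = np.empty((n, n))
    imputed = np.zeros((n, n), dtype=bool)
    n_missing = n - len(idx)
    if n_missing > 0:
        iu, ju = np.triu_indices(len(idx), k=1)
        if iu.size == 0:
            raise ValueError(
                "cannot impute similarities for DAG-less diseases: "
                "no computable disease pair exists"
            )
        S[:] = float(block[iu, ju].mean())
        miss = ~np.asarray(have)
        imputed[miss, :] = True
        imputed[:, miss] = True
        np.fill_diagonal(imputed, False)
    S[np.ix_(idx, idx)] = block
    np.fill_diagonal(S, 1.0)
    return DiseaseSimilarityMatrix(S=S, disease_ids=universe, imputed=imputed)
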