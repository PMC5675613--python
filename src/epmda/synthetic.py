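"""Synthetic benchmark generator.

Emulates the statistical structure the diffusion scorer assumes:
miRNAs fall into expression clusters (shared Gaussian template per
cluster plus per-miRNA noise across tissues), diseases sit on a rooted
term tree and are grouped into subtree-contiguous blocks, and each
cluster of miRNAs is associated with the diseases of one block.  A
fraction of associations is replaced by uniform noise pairs, and a
fraction of miRNAs loses its expression row, mimicking the incomplete
profile coverage of real expression databases.

The written files (associations.tsv, expression.tsv, dags.tsv,
truth.tsv) are exactly the formats the readers in the other modules
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .disease_similarity import DiseaseDAG, write_disease_dags
from .io import AssociationTable, write_association_table
from .mirna_similarity import ExpressionProfileMatrix, write_expression_profiles

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "write_dataset"]


@dataclass
class SyntheticSpec:
    """Generator parameters.

    The defaults yield 60 miRNAs in 6 expression clusters over 40
    tissues, 30 diseases on a binary term tree of depth 4, three
    planted associations per miRNA inside its cluster's disease block,
    10% noise associations and 10% missing expression profiles.
    """

    n_mirnas: int = 60
    n_diseases: int = 30
    n_tissues: int = 40
    n_clusters: int = 6
    dag_branching: int = 2
    dag_depth: int = 4
    dag_extra_edges: int = 0
    assoc_per_cluster: int = 3
    noise_assoc_fraction: float = 0.1
    expression_noise_sd: float = 0.5
    missing_profile_fraction: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_clusters > self.n_mirnas:
            raise ValueError("n_clusters cannot exceed n_mirnas")
        if min(self.n_mirnas, self.n_diseases, self.n_tissues, self.n_clusters) < 1:
            raise ValueError("counts must be positive")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues for Pearson similarity")
        if self.dag_branching < 1 or self.dag_depth < 1:
            raise ValueError("tree branching and depth must be >= 1")
        if not 0.0 <= self.noise_assoc_fraction < 1.0:
            raise ValueError("noise_assoc_fraction must lie in [0, 1)")
        if not 0.0 <= self.missing_profile_fraction < 1.0:
            raise ValueError("missing_profile_fraction must lie in [0, 1)")
        if self.expression_noise_sd < 0:
            raise ValueError("expression_noise_sd must be >= 0")
        if self.assoc_per_cluster < 1:
            raise ValueError("assoc_per_cluster must be >= 1")


@dataclass
class SyntheticDataset:
    expression: ExpressionProfileMatrix
    dags: list[DiseaseDAG]
    associations: AssociationTable
    truth: pd.DataFrame = field(repr=False)
    mirna_cluster: dict[str, int] = field(repr=False, default_factory=dict)
    cluster_diseases: dict[int, list[str]] = field(repr=False, default_factory=dict)


def _term_tree(branching: int, depth: int) -> tuple[list[str], dict[str, str], dict[str, int]]:
    """Full b-ary tree of term ids; returns (preorder nodes, parent map, depth map)."""
    parent: dict[str, str] = {}
    level: dict[str, int] = {"T0": 0}
    counter = 1
    order: list[str] = []

    def grow(node: str, d: int) -> None:
        nonlocal counter
        order.append(node)
        if d == depth:
            return
        for _ in range(branching):
            child = f"T{counter}"
            counter += 1
            parent[child] = node
            level[child] = d + 1
            grow(child, d + 1)

    grow("T0", 0)
    return order, parent, level


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset; all randomness comes from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    # term tree; diseases anchor at non-root nodes in preorder so that
    # consecutive diseases share deep ancestors
    order, parent, level = _term_tree(spec.dag_branching, spec.dag_depth)
    anchors = [t for t in order if t != "T0"]
    if spec.n_diseases > len(anchors):
        raise ValueError(
            f"term tree has only {len(anchors)} non-root nodes for "
            f"{spec.n_diseases} diseases; increase dag_branching or dag_depth"
        )
    disease_ids = [f"D{i + 1}" for i in range(spec.n_diseases)]
    anchor_of = dict(zip(disease_ids, anchors))

    extra_parents: dict[str, list[str]] = {}
    if spec.dag_extra_edges > 0:
        # cross-links child -> strictly shallower non-ancestor node keep acyclicity
        added = 0
        attempts = 0
        while added < spec.dag_extra_edges and attempts < 100 * spec.dag_extra_edges:
            attempts += 1
            u, v = rng.choice(order, size=2, replace=False)
            if level[v] >= level[u]:
                continue
            anc = set()
            t = u
            while t in parent:
                t = parent[t]
                anc.add(t)
            if v in anc or v in extra_parents.get(u, []):
                continue
            extra_parents.setdefault(u, []).append(v)
            added += 1

    def ancestor_closure(node: str) -> tuple[set[str], set[tuple[str, str]]]:
        terms: set[str] = set()
        edges: set[tuple[str, str]] = set()
        stack = [node]
        while stack:
            t = stack.pop()
            if t in terms:
                continue
            terms.add(t)
            for p in ([parent[t]] if t in parent else []) + extra_parents.get(t, []):
                edges.add((t, p))
                stack.append(p)
        return terms, edges

    dags = []
    for d in disease_ids:
        v = anchor_of[d]
        terms, edges = ancestor_closure(v)
        terms.add(d)
        edges.add((d, v))
        dags.append(DiseaseDAG(disease_id=d, terms=frozenset(terms), edges=frozenset(edges)))

    # subtree-contiguous disease blocks, one per cluster
    blocks = [list(b) for b in np.array_split(np.array(disease_ids), spec.n_clusters)]
    for c, b in enumerate(blocks):
        if len(b) < spec.assoc_per_cluster:
            raise ValueError(
                f"disease block {c} has {len(b)} diseases but assoc_per_cluster="
                f"{spec.assoc_per_cluster}; shrink assoc_per_cluster or clusters"
            )

    # clustered expression profiles
    mirna_ids = [f"m{i + 1}" for i in range(spec.n_mirnas)]
    cluster_of_idx = np.concatenate(
        [np.full(len(part), c) for c, part in
         enumerate(np.array_split(np.arange(spec.n_mirnas), spec.n_clusters))]
    )
    templates = rng.standard_normal((spec.n_clusters, spec.n_tissues))
    expr = templates[cluster_of_idx] + rng.normal(
        0.0, spec.expression_noise_sd, size=(spec.n_mirnas, spec.n_tissues)
    )

    # planted associations: each miRNA links to distinct diseases of its block
    records: list[tuple[str, str]] = []
    noise_flags: list[bool] = []
    for i, m in enumerate(mirna_ids):
        block = blocks[cluster_of_idx[i]]
        picks = rng.choice(len(block), size=spec.assoc_per_cluster, replace=False)
        for p in picks:
            records.append((m, block[p]))
            noise_flags.append(False)
    n_noise = int(round(spec.noise_assoc_fraction * len(records)))
    if n_noise > 0:
        noisy = rng.choice(len(records), size=n_noise, replace=False)
        for k in noisy:
            records[k] = (
                mirna_ids[rng.integers(spec.n_mirnas)],
                disease_ids[rng.integers(spec.n_diseases)],
            )
            noise_flags[k] = True

    seen: dict[tuple[str, str], int] = {}
    uniq_records: list[tuple[str, str]] = []
    uniq_noise: list[bool] = []
    for rec, flag in zip(records, noise_flags):
        if rec in seen:
            # a planted copy outranks a colliding noise copy
            uniq_noise[seen[rec]] = uniq_noise[seen[rec]] and flag
            continue
        seen[rec] = len(uniq_records)
        uniq_records.append(rec)
        uniq_noise.append(flag)
    table = AssociationTable(records=tuple(uniq_records))

    # drop expression rows for the missing fraction
    n_missing = int(round(spec.missing_profile_fraction * spec.n_mirnas))
    missing_idx = set(rng.choice(spec.n_mirnas, size=n_missing, replace=False).tolist())
    kept = [i for i in range(spec.n_mirnas) if i not in missing_idx]
    expression = ExpressionProfileMatrix(
        values=expr[kept],
        mirna_ids=[mirna_ids[i] for i in kept],
        tissue_ids=[f"tissue{t + 1}" for t in range(spec.n_tissues)],
    )

    truth = pd.DataFrame(
        {
            "mirna": [m for m, _ in uniq_records],
            "disease": [d for _, d in uniq_records],
            "is_noise": [int(f) for f in uniq_noise],
        }
    )
    return SyntheticDataset(
        expression=expression,
        dags=dags,
        associations=table,
        truth=truth,
        mirna_cluster={m: int(cluster_of_idx[i]) for i, m in enumerate(mirna_ids)},
        cluster_diseases={c: list(b) for c, b in enumerate(blocks)},
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write associations.tsv, expression.tsv, dags.tsv and truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "expression": outdir / "expression.tsv",
        "dags": outdir / "dags.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_association_table(dataset.associations, paths["associations"])
    write_expression_profiles(dataset.expression, paths["expression"])
    write_disease_dags(dataset.dags, paths["dags"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
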