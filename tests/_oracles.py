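"""Independent brute-force oracles used to check the vectorised code.

Everything here is written as literal per-element loops or exhaustive
enumeration, deliberately avoiding the matrix identities the package
uses, so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def loop_two_way_diffusion(A, A_d, A_m, alpha, beta):
    """Per-element evaluation of the two-step resource/feedback diffusion."""
    A = np.asarray(A, float)
    n_m, n_d = A.shape

    def colsum(X, j):
        return sum(X[t, j] for t in range(n_m))

    def rowsum(X, n):
        return sum(X[n, t] for t in range(n_d))

    def r1_mir(X, i):
        v = np.zeros(n_m)
        for j in range(n_d):
            c = colsum(X, j)
            if c != 0:
                v += (X[i, j] / c) * A[:, j]
        return v

    def r1_dis(X, m):
        v = np.zeros(n_d)
        for n in range(n_m):
            r = rowsum(X, n)
            if r != 0:
                v += (X[n, m] / r) * A[n, :]
        return v

    S1_mir = np.array([alpha * r1_mir(A_d, i) + (1 - alpha) * r1_mir(A_m, i)
                       for i in range(n_m)])
    S1_dis = np.array([beta * r1_dis(A_d, m) + (1 - beta) * r1_dis(A_m, m)
                       for m in range(n_d)])

    def r2_mir(X, i):
        v = np.zeros(n_d)
        for j in range(n_d):
            c = colsum(X, j)
            if c != 0:
                v += (X[i, j] / c) * S1_dis[j]
        return v

    def r2_dis(X, m):
        v = np.zeros(n_m)
        for n in range(n_m):
            r = rowsum(X, n)
            if r != 0:
                v += (X[n, m] / r) * S1_mir[n]
        return v

    S2_mir = np.array([alpha * r2_mir(A_d, i) + (1 - alpha) * r2_mir(A_m, i)
                       for i in range(n_m)])
    S2_dis = np.array([beta * r2_dis(A_d, m) + (1 - beta) * r2_dis(A_m, m)
                       for m in range(n_d)])

    SS = np.empty((n_m, n_d))
    for i in range(n_m):
        for j in range(n_d):
            SS[i, j] = (S2_mir[i, j] + S2_dis[j, i]) / 2.0
    return SS


def enumerate_contribution(dag, delta):
    """Contribution of each term by exhaustive descending-path enumeration.

    For every term, enumerate all simple paths down the child edges to
    the disease term and take delta to the minimum path length.
    """
    children = {}
    for c, p in dag.edges:
        children.setdefault(p, []).append(c)

    def all_path_lengths(t):
        if t == dag.term:
            return [0]
        lengths = []
        for c in children.get(t, []):
            lengths.extend(1 + l for l in all_path_lengths(c))
        return lengths

    contrib = {}
    for t in dag.terms:
        lengths = all_path_lengths(t)
        if not lengths:
            raise ValueError(f"term {t} has no descending path to {dag.term}")
        contrib[t] = delta ** min(lengths)
    return contrib


def pair_semantic_similarity(contrib_i, contrib_j):
    shared = set(contrib_i) & set(contrib_j)
    if not shared:
        return 0.0
    num = sum(contrib_i[t] + contrib_j[t] for t in shared)
    den = sum(contrib_i.values()) + sum(contrib_j.values())
    return num / den


def concordance_auc(scores, labels):
    """O(n^2) Mann-Whitney AUC: P(pos > neg) + 0.5 P(pos = neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            total += 1.0
        elif p == n:
            total += 0.5
    return total / (len(pos) * len(neg))


def walk_count_katz(H, beta, max_length, lmin=2):
    """Damped walk-weight sums by dynamic programming with explicit loops."""
    H = np.asarray(H, float)
    n = H.shape[0]
    total = np.zeros((n, n))
    walks = H.copy()  # weight of walks of length 1
    for length in range(2, max_length + 1):
        nxt = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                acc = 0.0
                for mid in range(n):
                    acc += walks[a, mid] * H[mid, b]
                nxt[a, b] = acc
        walks = nxt
        if length >= lmin:
            total += beta**length * walks
    if lmin <= 1:
        total += beta * H
    return total


def loop_user_cf(A, S):
    A = np.asarray(A, float)
    S = np.asarray(S, float)
    n_m, n_d = A.shape
    out = np.zeros((n_m, n_d))
    for i in range(n_m):
        den = sum(abs(S[i, k]) for k in range(n_m) if k != i)
        for j in range(n_d):
            num = sum(S[i, k] * A[k, j] for k in range(n_m) if k != i)
            out[i, j] = num / den if den != 0 else 0.0
    return out


def loop_item_cf(A, S):
    A = np.asarray(A, float)
    S = np.asarray(S, float)
    n_m, n_d = A.shape
    out = np.zeros((n_m, n_d))
    for j in range(n_d):
        den = sum(abs(S[l, j]) for l in range(n_d) if l != j)
        for i in range(n_m):
            num = sum(A[i, l] * S[l, j] for l in range(n_d) if l != j)
            out[i, j] = num / den if den != 0 else 0.0
    return out


def random_dag_forest(rng, n_diseases, max_terms=30):
    """Random forest of disease DAGs for oracle comparisons.

    Builds a shared random tree (with occasional extra cross edges) of
    at most ``max_terms`` terms and anchors each disease at a random
    non-root node.
    """
    from epmda.disease_similarity import DiseaseDAG

    n_terms = int(rng.integers(3, max_terms + 1))
    parent = {}
    for k in range(1, n_terms):
        parent[f"t{k}"] = f"t{int(rng.integers(0, k))}"
    extra = {}
    for _ in range(int(rng.integers(0, 3))):
        a, b = rng.integers(0, n_terms, size=2)
        if a > b:  # edge from later to earlier node keeps acyclicity
            extra.setdefault(f"t{a}", set()).add(f"t{b}")

    dags = []
    for d in range(n_diseases):
        anchor = f"t{int(rng.integers(1, n_terms))}"
        terms = {f"D{d}"}
        edges = {(f"D{d}", anchor)}
        stack = [anchor]
        while stack:
            t = stack.pop()
            if t in terms:
                continue
            terms.add(t)
            ups = ([parent[t]] if t in parent else []) + sorted(extra.get(t, ()))
            for p in ups:
                edges.add((t, p))
                stack.append(p)
        dags.append(DiseaseDAG(disease_id=f"D{d}", terms=frozenset(terms),
                               edges=frozenset(edges)))
    return dags
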