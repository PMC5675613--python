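import numpy as np
import pytest

from _oracles import (
    enumerate_contribution,
    pair_semantic_similarity,
    random_dag_forest,
)
from epmda.disease_similarity import (
    DiseaseDAG,
    build_disease_similarity,
    read_disease_dags,
    semantic_contribution,
    semantic_similarity,
    write_disease_dags,
)


def chain_dag(disease, *ancestors):
    """disease -> ancestors[0] -> ancestors[1] -> ..."""
    nodes = [disease, *ancestors]
    edges = {(nodes[k], nodes[k + 1]) for k in range(len(nodes) - 1)}
    return DiseaseDAG(disease_id=disease, terms=frozenset(nodes), edges=frozenset(edges))


class TestSemanticContribution:
    def test_disease_term_contributes_one(self):
        c = semantic_contribution(chain_dag("d", "b", "a"), delta=0.5)
        assert c.contrib["d"] == 1.0

    def test_direct_parent_decays_once(self):
        c = semantic_contribution(chain_dag("d", "p"), delta=0.5)
        assert c.contrib["p"] == 0.5

    def test_multiple_paths_take_minimum_length(self):
        # x reaches d both directly through p (2 edges) and through q,r (3 edges)
        dag = DiseaseDAG(
            disease_id="d",
            terms=frozenset({"d", "p", "q", "r", "x"}),
            edges=frozenset({("d", "p"), ("p", "x"), ("d", "q"), ("q", "r"), ("r", "x")}),
        )
        c = semantic_contribution(dag, delta=0.5)
        assert c.contrib["x"] == pytest.approx(0.5**2)
        assert c.contrib == enumerate_contribution(dag, 0.5)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG(
                disease_id="d", terms=frozenset({"d", "a", "b"}),
                edges=frozenset({("d", "a"), ("a", "b"), ("b", "a")}),
            )

    def test_unreachable_term_rejected(self):
        dag = DiseaseDAG(
            disease_id="d", terms=frozenset({"d", "a", "z"}),
            edges=frozenset({("d", "a"), ("z", "a")}),
        )
        with pytest.raises(ValueError, match="descending path"):
            semantic_contribution(dag, 0.5)

    def test_delta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            semantic_contribution(chain_dag("d", "p"), delta=1.0)


class TestSemanticSimilarity:
    def test_identical_dags_similarity_one(self):
        d1 = DiseaseDAG("d1", frozenset({"t", "a"}), frozenset({("t", "a")}), term="t")
        d2 = DiseaseDAG("d2", frozenset({"t", "a"}), frozenset({("t", "a")}), term="t")
        c1 = semantic_contribution(d1, 0.5)
        c2 = semantic_contribution(d2, 0.5)
        assert semantic_similarity(c1, c2) == pytest.approx(1.0)

    def test_disjoint_term_sets_similarity_zero(self):
        c1 = semantic_contribution(chain_dag("d1", "a1"), 0.5)
        c2 = semantic_contribution(chain_dag("d2", "a2"), 0.5)
        assert semantic_similarity(c1, c2) == 0.0

    def test_shared_sole_parent_is_one_third(self):
        # both DAGs are 2-term chains through the same parent a:
        # shared mass 0.5+0.5 over total (1+0.5)+(1+0.5)
        c1 = semantic_contribution(chain_dag("d1", "a"), 0.5)
        c2 = semantic_contribution(chain_dag("d2", "a"), 0.5)
        assert semantic_similarity(c1, c2) == pytest.approx(1.0 / 3.0)

    def test_adding_shared_ancestor_never_decreases_similarity(self):
        base1 = chain_dag("d1", "a")
        base2 = chain_dag("d2", "a")
        c1, c2 = (semantic_contribution(d, 0.5) for d in (base1, base2))
        before = semantic_similarity(c1, c2)
        ext1 = chain_dag("d1", "a", "root")
        ext2 = chain_dag("d2", "a", "root")
        c1e, c2e = (semantic_contribution(d, 0.5) for d in (ext1, ext2))
        assert semantic_similarity(c1e, c2e) >= before

    def test_small_delta_drives_distinct_diseases_to_zero(self):
        sims = []
        for delta in (0.5, 0.1, 0.01, 0.001):
            c1 = semantic_contribution(chain_dag("d1", "a"), delta)
            c2 = semantic_contribution(chain_dag("d2", "a"), delta)
            sims.append(semantic_similarity(c1, c2))
        assert sims == sorted(sims, reverse=True)
        assert sims[-1] < 1e-3


class TestBuildMatrix:
    def test_identity_for_pairwise_disjoint_dags(self):
        dags = [chain_dag(f"d{k}", f"a{k}") for k in range(3)]
        sm = build_disease_similarity(dags, [f"d{k}" for k in range(3)], 0.5)
        np.testing.assert_allclose(sm.S, np.eye(3))

    def test_duplicate_dag_rejected(self):
        dags = [chain_dag("d1", "a"), chain_dag("d1", "b")]
        with pytest.raises(ValueError, match="duplicate"):
            build_disease_similarity(dags, ["d1"], 0.5)

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 6))
            dags = random_dag_forest(rng, n)
            universe = [d.disease_id for d in dags]
            sm = build_disease_similarity(dags, universe, 0.5)
            contribs = [enumerate_contribution(d, 0.5) for d in dags]
            for a in range(n):
                for b in range(n):
                    expected = (
                        1.0 if a == b
                        else pair_semantic_similarity(contribs[a], contribs[b])
                    )
                    assert sm.S[a, b] == pytest.approx(expected, abs=1e-12)

    def test_missing_dag_gets_mean_of_computable_pairs(self, rng):
        dags = random_dag_forest(rng, 4)
        universe = [d.disease_id for d in dags] + ["orphan"]
        sm = build_disease_similarity(dags, universe, 0.5)
        iu, ju = np.triu_indices(4, k=1)
        expected = sm.S[iu, ju].mean()
        np.testing.assert_allclose(sm.S[4, :4], expected, atol=1e-12)
        assert sm.S[4, 4] == 1.0
        assert sm.imputed[4, :4].all() and not sm.imputed[:4, :4].any()

    def test_symmetry_unit_diagonal_and_range(self, rng):
        dags = random_dag_forest(rng, 6)
        sm = build_disease_similarity(dags, [d.disease_id for d in dags], 0.5)
        np.testing.assert_allclose(sm.S, sm.S.T)
        np.testing.assert_allclose(np.diag(sm.S), 1.0)
        assert ((sm.S >= 0) & (sm.S <= 1)).all()


def test_dag_file_roundtrip(rng, tmp_path):
    dags = random_dag_forest(rng, 5)
    path = tmp_path / "dags.tsv"
    write_disease_dags(dags, path)
    back = {d.disease_id: d for d in read_disease_dags(path)}
    assert set(back) == {d.disease_id for d in dags}
    for d in dags:
        assert back[d.disease_id].terms == d.terms
        assert back[d.disease_id].edges == d.edges
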