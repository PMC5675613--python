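"""Semantic similarity of two diseases from hand-built term DAGs.

Asthma-like toy example: two diseases hang under a shared parent term;
each term's contribution decays by delta=0.5 per level away from the
disease, and similarity is the shared contribution mass over the total.
"""

from epmda import DiseaseDAG, semantic_contribution, semantic_similarity

lung_a = DiseaseDAG(
    disease_id="disease_A",
    terms=frozenset({"disease_A", "airway_obstruction", "respiratory_disease"}),
    edges=frozenset({("disease_A", "airway_obstruction"),
                     ("airway_obstruction", "respiratory_disease")}),
)
lung_b = DiseaseDAG(
    disease_id="disease_B",
    terms=frozenset({"disease_B", "airway_obstruction", "respiratory_disease"}),
    edges=frozenset({("disease_B", "airway_obstruction"),
                     ("airway_obstruction", "respiratory_disease")}),
)

ca = semantic_contribution(lung_a, delta=0.5)
cb = semantic_contribution(lung_b, delta=0.5)
print("contributions to disease_A:")
for term, value in sorted(ca.contrib.items(), key=lambda kv: -kv[1]):
    print(f"  {term:<22s} {value:.3f}")

sim = semantic_similarity(ca, cb)
print(f"\nsimilarity(disease_A, disease_B) = {sim:.4f}")
print("(shared ancestors contribute 2*(0.5+0.25) over total 2*1.75)")
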