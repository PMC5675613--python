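import numpy as np
import pytest

from _oracles import loop_two_way_diffusion
from conftest import random_association, random_similarity
from epmda.diffusion import (
    build_weighted_networks,
    diffusion_shares,
    epmda_scores,
    predict,
    two_way_diffusion,
)
from epmda.io import RunConfig
from epmda.synthetic import SyntheticSpec, generate, write_dataset


class TestWeightedNetworks:
    def test_identity_similarities_leave_network_unchanged(self, rng):
        A = random_association(rng, 5, 4)
        nets = build_weighted_networks(A, np.eye(4), np.eye(5))
        np.testing.assert_array_equal(nets.A_d, A)
        np.testing.assert_array_equal(nets.A_m, A)

    def test_all_ones_disease_similarity_broadcasts_row_sums(self, rng):
        A = random_association(rng, 5, 4)
        nets = build_weighted_networks(A, np.ones((4, 4)), np.eye(5))
        np.testing.assert_allclose(nets.A_d, np.tile(A.sum(axis=1)[:, None], (1, 4)))

    def test_matches_triple_loop_product(self, rng):
        A = random_association(rng, 4, 3)
        Sd = random_similarity(rng, 3)
        Sm = random_similarity(rng, 4)
        nets = build_weighted_networks(A, Sd, Sm)
        Ad = np.array([[sum(A[i, l] * Sd[l, j] for l in range(3)) for j in range(3)]
                       for i in range(4)])
        Am = np.array([[sum(Sm[i, k] * A[k, j] for k in range(4)) for j in range(3)]
                       for i in range(4)])
        np.testing.assert_allclose(nets.A_d, Ad, atol=1e-12)
        np.testing.assert_allclose(nets.A_m, Am, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        A = random_association(rng, 4, 3)
        with pytest.raises(ValueError):
            build_weighted_networks(A, np.eye(4), np.eye(4))


class TestDiffusionShares:
    def test_direct_normalization(self):
        W, M = diffusion_shares(np.array([[1.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_allclose(W, [[0.5, 1.0], [0.5, 0.0]])
        np.testing.assert_allclose(M, [[0.5, 0.5], [1.0, 0.0]])

    def test_zero_column_gives_zero_shares_not_nan(self):
        W, M = diffusion_shares(np.array([[1.0, 0.0], [1.0, 0.0]]))
        assert np.isfinite(W).all()
        np.testing.assert_array_equal(W[:, 1], 0.0)

    def test_nonzero_columns_and_rows_sum_to_one(self, rng):
        A_w = rng.random((6, 4)) * (rng.random((6, 4)) < 0.6)
        W, M = diffusion_shares(A_w)
        for j in range(4):
            if A_w[:, j].sum() > 0:
                assert W[:, j].sum() == pytest.approx(1.0, abs=1e-12)
        for i in range(6):
            if A_w[i].sum() > 0:
                assert M[i].sum() == pytest.approx(1.0, abs=1e-12)


class TestTwoWayDiffusion:
    def test_all_zero_associations_give_zero_scores(self):
        A = np.zeros((4, 3))
        nets = build_weighted_networks(A, np.eye(3), np.eye(4))
        np.testing.assert_array_equal(two_way_diffusion(A, nets), 0.0)

    def test_alpha_beta_one_is_pure_disease_stream(self, rng):
        A = random_association(rng, 6, 4)
        Sd, Sm = random_similarity(rng, 4), random_similarity(rng, 6)
        nets = build_weighted_networks(A, Sd, Sm)
        full = two_way_diffusion(A, nets, alpha=1.0, beta=1.0)
        # replacing the miRNA-weighted stream by garbage must not matter
        nets_d_only = build_weighted_networks(A, Sd, random_similarity(rng, 6))
        np.testing.assert_allclose(
            full, two_way_diffusion(A, nets_d_only, alpha=1.0, beta=1.0), atol=1e-12
        )

    def test_matches_elementwise_loop_oracle(self, rng):
        for _ in range(5):
            n_m, n_d = int(rng.integers(2, 9)), int(rng.integers(2, 7))
            A = random_association(rng, n_m, n_d)
            nets = build_weighted_networks(
                A, random_similarity(rng, n_d), random_similarity(rng, n_m)
            )
            got = two_way_diffusion(A, nets, 0.5, 0.5)
            want = loop_two_way_diffusion(A, nets.A_d, nets.A_m, 0.5, 0.5)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_scale_invariance_of_similarity_matrices(self, rng):
        A = random_association(rng, 7, 5)
        Sd, Sm = random_similarity(rng, 5), random_similarity(rng, 7)
        base = epmda_scores(A, Sm, Sd)
        scaled = epmda_scores(A, 3.7 * Sm, 0.2 * Sd)
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_scores_affine_in_alpha_and_beta(self, rng):
        A = random_association(rng, 6, 5)
        Sd, Sm = random_similarity(rng, 5), random_similarity(rng, 6)
        nets = build_weighted_networks(A, Sd, Sm)
        for fixed_beta in (0.3,):
            s0 = two_way_diffusion(A, nets, 0.0, fixed_beta)
            s5 = two_way_diffusion(A, nets, 0.5, fixed_beta)
            s1 = two_way_diffusion(A, nets, 1.0, fixed_beta)
            np.testing.assert_allclose(s5, (s0 + s1) / 2, atol=1e-10)
        for fixed_alpha in (0.8,):
            s0 = two_way_diffusion(A, nets, fixed_alpha, 0.0)
            s5 = two_way_diffusion(A, nets, fixed_alpha, 0.5)
            s1 = two_way_diffusion(A, nets, fixed_alpha, 1.0)
            np.testing.assert_allclose(s5, (s0 + s1) / 2, atol=1e-10)

    def test_deterministic(self, rng):
        A = random_association(rng, 6, 4)
        nets = build_weighted_networks(
            A, random_similarity(rng, 4), random_similarity(rng, 6)
        )
        a = two_way_diffusion(A, nets)
        b = two_way_diffusion(A, nets)
        assert (a == b).all()

    def test_invalid_damping_rejected(self, rng):
        A = random_association(rng, 3, 3)
        nets = build_weighted_networks(A, np.eye(3), np.eye(3))
        with pytest.raises(ValueError):
            two_way_diffusion(A, nets, alpha=1.2)


@pytest.fixture(scope="module")
def small_files(tmp_path_factory):
    spec = SyntheticSpec(n_mirnas=12, n_diseases=10, n_tissues=15,
                         n_clusters=2, assoc_per_cluster=2, seed=7)
    return write_dataset(generate(spec), tmp_path_factory.mktemp("small"))


class TestPredictPipeline:
    def test_smoke_shape_and_finiteness(self, small_files):
        score = predict(small_files["associations"], small_files["expression"],
                        small_files["dags"])
        assert score.SS.shape == (len(score.mirna_ids), len(score.disease_ids))
        assert np.isfinite(score.SS).all()

    def test_composition_identity(self, small_files):
        from epmda.disease_similarity import build_disease_similarity, read_disease_dags
        from epmda.io import build_association_matrix, read_association_table
        from epmda.mirna_similarity import build_mirna_similarity, read_expression_profiles

        score = predict(small_files["associations"], small_files["expression"],
                        small_files["dags"], RunConfig())
        amat = build_association_matrix(read_association_table(small_files["associations"]))
        sm_mir = build_mirna_similarity(
            read_expression_profiles(small_files["expression"]), amat.mirna_ids
        )
        sm_dis = build_disease_similarity(
            read_disease_dags(small_files["dags"]), amat.disease_ids, 0.5
        )
        np.testing.assert_array_equal(score.SS, epmda_scores(amat.A, sm_mir, sm_dis))

    def test_input_row_order_does_not_matter(self, small_files, rng, tmp_path):
        score = predict(small_files["associations"], small_files["expression"],
                        small_files["dags"])

        lines = [l for l in small_files["associations"].read_text().splitlines()
                 if l and not l.startswith("#")]
        rng.shuffle(lines)
        shuffled = tmp_path / "shuffled.tsv"
        shuffled.write_text("\n".join(lines) + "\n")
        score2 = predict(shuffled, small_files["expression"], small_files["dags"])

        ri = [score2.mirna_ids.index(m) for m in score.mirna_ids]
        cj = [score2.disease_ids.index(d) for d in score.disease_ids]
        np.testing.assert_allclose(score.SS, score2.SS[np.ix_(ri, cj)], atol=1e-12)
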