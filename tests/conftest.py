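import numpy as np
import pytest

from epmda import (
    build_association_matrix,
    build_disease_similarity,
    build_mirna_similarity,
)
from epmda.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20240913)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic benchmark (seed 42), generated once per session."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def default_inputs(default_dataset):
    """Association matrix plus both similarity matrices for the default benchmark."""
    ds = default_dataset
    amat = build_association_matrix(ds.associations)
    sm_mir = build_mirna_similarity(ds.expression, amat.mirna_ids)
    sm_dis = build_disease_similarity(ds.dags, amat.disease_ids, delta=0.5)
    return amat, sm_mir, sm_dis


def random_association(rng, n_m, n_d, density=0.3):
    """Random binary matrix with at least one positive and one negative entry."""
    while True:
        A = (rng.random((n_m, n_d)) < density).astype(float)
        if 0 < A.sum() < A.size:
            return A


def random_similarity(rng, n):
    """Random symmetric unit-diagonal matrix with entries in [0, 1]."""
    S = rng.random((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S
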