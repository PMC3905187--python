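import numpy as np
import pytest

import hexsom as hx
from hexsom.trainer import Codebook, InputMatrix


@pytest.fixture(scope="session")
def map_r3():
    return hx.build_map(3)


@pytest.fixture(scope="session")
def map_r8():
    return hx.build_map(8)


def random_codebook(spec, n_samples, rng):
    return Codebook(
        prototypes=rng.normal(size=(spec.node_count, n_samples)),
        spec=spec,
        col_ids=[f"s{j}" for j in range(n_samples)],
    )


def random_input(n_genes, n_samples, rng):
    return InputMatrix(
        values=rng.normal(size=(n_genes, n_samples)),
        row_ids=[f"g{i}" for i in range(n_genes)],
        col_ids=[f"s{j}" for j in range(n_samples)],
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """The seeded planted-cluster world: 600 genes, 6 samples, 4 clusters,
    30% background, centroid scale 3, noise 0.3."""
    return hx.generate(hx.SyntheticSpec(600, 6, 4, 0.3, 3.0, 0.3, seed=7))


@pytest.fixture(scope="session")
def trained_fixture(planted_fixture):
    """Map trained on the planted fixture at the automatic radius."""
    from hexsom.trainer import train_on_matrix

    return train_on_matrix(planted_fixture.matrix, seed=7)
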