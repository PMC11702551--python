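import numpy as np
import pytest

from rxbench import (
    IndicationMapping,
    InteractionMatrix,
    SyntheticConfig,
    build_similarity_lists,
    generate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_matrix(rng):
    """5 compounds x 4 proteins with generic random scores."""
    return InteractionMatrix(
        [f"c{i}" for i in range(5)],
        [f"p{j}" for j in range(4)],
        rng.random((5, 4)),
    )


@pytest.fixture
def small_lists(small_matrix):
    return build_similarity_lists(small_matrix)


@pytest.fixture
def planted_zero_noise():
    """50 compounds, 5 disjoint 4-drug indications, zero noise."""
    return generate(
        SyntheticConfig(
            n_compounds=50, n_proteins=20, n_indications=5,
            drugs_per_indication=4, noise_sd=0.0, seed=7,
        )
    )


@pytest.fixture
def planted_noisy():
    """Moderate-noise planted clusters: recoverable but not trivial."""
    return generate(
        SyntheticConfig(
            n_compounds=50, n_proteins=20, n_indications=5,
            drugs_per_indication=4, noise_sd=0.08, seed=11,
        )
    )


def random_instance(rng, n_compounds, n_proteins):
    """A random matrix plus its ids/scores in plain-Python form for oracles."""
    ids = [f"c{i:02d}" for i in range(n_compounds)]
    scores = rng.random((n_compounds, n_proteins))
    matrix = InteractionMatrix(ids, [f"p{j}" for j in range(n_proteins)], scores)
    return matrix, ids, [list(map(float, row)) for row in scores]


def toy_mapping(drug_sets, library):
    return IndicationMapping(
        [(d, ind) for ind, drugs in drug_sets.items() for d in drugs],
        drug_library=library,
    )
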