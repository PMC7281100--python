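import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from pathmet import (
    MetabolicModel,
    Parameters,
    generate_random_model,
    generate_synthetic_dataset,
    make_figure1_fixture,
)


@pytest.fixture(scope="session")
def fig1():
    """The packaged two-pathway worked example (model, observation vector)."""
    return make_figure1_fixture()


@pytest.fixture
def tiny_model():
    """A 2-pathway, 4-metabolite model small enough for full Z enumeration.

    One mass collision (m3, m4 share a bin), one shared metabolite (m2 on
    both pathways), one metabolite on no pathway reachable by varying
    membership in tests.
    """
    membership = np.array(
        [
            [1, 1, 1, 0],
            [0, 1, 0, 1],
        ],
        dtype=np.uint8,
    )
    return MetabolicModel.from_masses(
        pathway_ids=["p1", "p2"],
        metabolite_ids=["m1", "m2", "m3", "m4"],
        metabolite_mass=[100.0, 200.0, 300.0, 300.0015],
        membership=membership,
        ppm_tol=15.0,
    )


def random_small_model(rng, max_pathways=8, max_metabolites=30):
    """Random model with collisions for oracle-agreement tests."""
    i = int(rng.integers(3, max_pathways + 1))
    j = int(rng.integers(10, max_metabolites + 1))
    return generate_random_model(
        n_pathways=i,
        n_metabolites=j,
        mean_pathway_size=min(5.0, j / 2),
        mass_collision_fraction=0.2,
        seed=rng,
    )


def random_observation(model, rng, gamma=0.9):
    """Synthetic observation vector guaranteed attainable under the model."""
    data = generate_synthetic_dataset(model, 0.5, 0.4, gamma, seed=rng)
    return data


@pytest.fixture
def default_params():
    return Parameters(seed=0)
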