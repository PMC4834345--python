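import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import macanet as mn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> mn.InteractionMatrix:
    """3-node directed matrix used in several hand-computed examples."""
    return mn.InteractionMatrix(
        ["A", "B", "C"], np.array([[0, 2, 0], [1, 0, 3], [0, 0, 0]]), "other"
    )


@pytest.fixture
def wins_matrix() -> mn.InteractionMatrix:
    """Agonistic wins matrix of the worked David's Score example."""
    return mn.InteractionMatrix(
        ["A", "B", "C"], np.array([[0, 5, 4], [1, 0, 3], [0, 1, 0]]), "agonistic"
    )


def random_interaction_matrix(
    rng: np.random.Generator, n: int, max_count: int = 6, density: float = 0.7
) -> mn.InteractionMatrix:
    counts = rng.integers(1, max_count + 1, (n, n)) * (rng.random((n, n)) < density)
    np.fill_diagonal(counts, 0)
    ids = [f"n{k}" for k in range(n)]
    return mn.InteractionMatrix(ids, counts, "other")


@pytest.fixture
def small_troop():
    """A small planted-effects troop, cheap enough for unit tests."""
    cfg = mn.GeneratorConfig(
        n=30, n_female=15, n_matrilines=5, n_unassigned_male=3, n_unassigned_female=1
    )
    attrs, ago, gro, latent = mn.generate_dataset(cfg, seed=11)
    return cfg, attrs, ago, gro, latent
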