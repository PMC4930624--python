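import numpy as np
import pytest

from giniclust import ExpressionMatrix, simulate_nb_clusters


@pytest.fixture(scope="session")
def nb_benchmark():
    """Full-size five-cluster NB benchmark (matrix, truth), one fixed seed."""
    return simulate_nb_clusters(seed=0)


@pytest.fixture(scope="session")
def small_nb():
    """Smaller NB benchmark for fast pipeline-level tests."""
    return simulate_nb_clusters(
        cluster_sizes=(300, 300, 4, 6, 10), n_genes=3000,
        n_shuffle_high=50, n_shuffle_low=50, seed=2,
    )


@pytest.fixture()
def tiny_counts():
    values = np.array(
        [
            [0, 2, 3, 0],
            [1, 1, 1, 1],
            [0, 0, 5, 9],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"], "umi"
    )
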