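import numpy as np
import pytest

from moistnet import GridSpec, MoistureNetwork


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(4, 6, 10.0)


def make_network(n_nodes: int, edges) -> MoistureNetwork:
    """A network on a 1 x n strip grid, for purely topological tests."""
    grid = GridSpec(1, n_nodes, min(1.0, 360.0 / n_nodes))
    return MoistureNetwork(
        grid=grid,
        edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2),
        rho=0.25,
        captured_fraction=0.25,
    )


def random_network(n: int, p: float, rng: np.random.Generator) -> MoistureNetwork:
    A = rng.random((n, n)) < p
    np.fill_diagonal(A, False)
    return make_network(n, np.argwhere(A))
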