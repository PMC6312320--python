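import numpy as np
import pytest

from psistop.psi import ParameterGrid, Posterior


@pytest.fixture
def tiny_grid():
    """3 x 2 x 2 logistic threshold grid, small enough for brute-force oracles."""
    return ParameterGrid(
        primary=np.array([100.0, 200.0, 300.0]),
        slope=np.array([0.01, 0.02]),
        error_rate=np.array([0.0, 0.1]),
        primary_name="threshold",
    )


@pytest.fixture
def two_cell_grid():
    """Two cells differing only in threshold (single slope / error rate)."""
    return ParameterGrid(
        primary=np.array([100.0, 300.0]),
        slope=np.array([0.01]),
        error_rate=np.array([0.0]),
        primary_name="threshold",
    )


def random_posterior(grid, rng) -> Posterior:
    mass = rng.random(grid.n_cells) + 1e-6
    return Posterior(grid, mass / mass.sum())
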