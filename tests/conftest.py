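import numpy as np
import pytest

import ccsn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_expression(rng, n_genes, n_cells, zero_fraction=0.0):
    """Uniform random expression matrix, optionally zero-inflated."""
    values = rng.uniform(0.1, 5.0, size=(n_genes, n_cells))
    if zero_fraction > 0:
        values[rng.uniform(size=values.shape) < zero_fraction] = 0.0
    return ccsn.ExpressionMatrix(
        values,
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
    )


@pytest.fixture(scope="session")
def comm_dataset():
    """Shared two-cell-type dataset with one planted ligand-receptor pair."""
    spec = ccsn.default_communication_spec(seed=7)
    expr, ann = ccsn.generate_expression(spec)
    return spec, expr, ann
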