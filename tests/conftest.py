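import numpy as np
import pytest

from scheter import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, observed=None, tumors=None, genes=None, cells=None,
                cell_types=None):
    """Small helper to assemble an ExpressionMatrix from arrays."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i+1}" for i in range(n_genes)]
    cells = cells or [f"c{j+1}" for j in range(n_cells)]
    if observed is None:
        observed = np.ones_like(values, dtype=bool)
    if tumors is None:
        tumors = ["T1"] * n_cells
    tumor_of = dict(zip(cells, tumors))
    cell_type_of = dict(zip(cells, cell_types)) if cell_types else None
    return ExpressionMatrix(genes, cells, values, observed, tumor_of, cell_type_of)


@pytest.fixture
def masked_matrix(rng):
    """Random 20x30 matrix with ~25% missing entries across two tumors."""
    values = rng.normal(size=(20, 30))
    observed = rng.random((20, 30)) > 0.25
    observed[:, 0] = True  # keep every gene observed at least once
    tumors = ["A"] * 15 + ["B"] * 15
    return make_matrix(values, observed, tumors)
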