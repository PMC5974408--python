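import numpy as np
import pytest

from sldsf.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 6-sample x 10-gene expression matrix with named identifiers."""
    values = rng.normal(5.0, 2.0, size=(6, 10))
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"GENE{j}" for j in range(10)],
        sample_ids=[f"sample{i}" for i in range(6)],
    )


def permuted_matrix(matrix: ExpressionMatrix, perm) -> ExpressionMatrix:
    """The same expression data with gene columns reordered by ``perm``."""
    return ExpressionMatrix(
        values=matrix.values[:, perm],
        gene_ids=[matrix.gene_ids[j] for j in perm],
        sample_ids=list(matrix.sample_ids),
    )
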