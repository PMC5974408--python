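"""Per-sample standardization of the raw expression matrix.

The raw matrix B (samples x genes) is rescaled row by row to zero mean and
unit standard deviation, removing between-sample scale ("dimensional")
effects before sparse filtering:

    X = (B - mean(B, by row)) / std(B, by row)

Constant rows carry no differential signal; they map to all-zeros rather
than dividing by zero.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import ExpressionMatrix

# Sample (n-1) vs population (n) standard deviation.  The convention is
# switchable here and nowhere else.
STD_DDOF = 1

_ZERO_VAR_TOL = 1e-12


def _sorted_row_sum(values: np.ndarray, m: int) -> np.ndarray:
    """Row sums over value-sorted, contiguous entries.

    Both the operand order and the memory layout seen by the reduction are
    then fixed, so the result is bitwise invariant to column permutations
    of ``values``.
    """
    return np.ascontiguousarray(np.sort(values, axis=1)).sum(axis=1, keepdims=True)


def standardize(B: ExpressionMatrix) -> ExpressionMatrix:
    """Row-standardize an expression matrix.

    Returns a new :class:`ExpressionMatrix` whose non-constant rows have
    mean 0 (within 1e-8) and standard deviation 1 (within 1e-6).  Gene and
    sample identifiers are carried through unchanged.
    """
    values = B.values
    m = values.shape[1]
    # Row moments are accumulated over value-sorted entries, so the result
    # is bitwise invariant to the order of the gene columns.
    mean = _sorted_row_sum(values, m) / m
    std = np.sqrt(_sorted_row_sum((values - mean) ** 2, m) / (m - STD_DDOF))
    constant = std < _ZERO_VAR_TOL
    if constant.any():
        which = [B.sample_ids[i] for i in np.flatnonzero(constant.ravel())]
        warnings.warn(
            f"constant expression rows mapped to zeros: {which[:5]}",
            RuntimeWarning,
            stacklevel=2,
        )
        std = np.where(constant, 1.0, std)
    X = (values - mean) / std
    return ExpressionMatrix(values=X, gene_ids=list(B.gene_ids), sample_ids=list(B.sample_ids))
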