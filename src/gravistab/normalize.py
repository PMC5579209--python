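"""Log2 transform and quantile normalization of expression matrices.

Quantile normalization equalizes the intensity distribution across arrays of
one platform: the highest value on each array is replaced by the mean of the
per-array highest values, then the second highest, and so on. Each column's
rank order is preserved; after normalization every column has exactly the
same sorted value vector. Normalization is always performed within a
platform, never pooled across platforms.
"""

from __future__ import annotations

import numpy as np

from .matrixio import LINEAR, LOG2, ExpressionMatrix, ValidationError

__all__ = ["log2_transform", "quantile_normalize"]


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix with every linear intensity replaced by its log2.

    Raises :class:`ValidationError` if the matrix is not linear-scale or
    contains a non-positive value (the offending gene/sample is named).
    """
    if matrix.scale != LINEAR:
        raise ValidationError(
            f"log2_transform expects a linear-scale matrix, got {matrix.scale!r}"
        )
    values = matrix.data.to_numpy(dtype=float)
    if values.size and values.min() <= 0:
        g, s = np.argwhere(values <= 0)[0]
        raise ValidationError(
            f"non-positive value at gene {matrix.data.index[g]!r}, "
            f"sample {matrix.data.columns[s]!r}: cannot take log2"
        )
    return matrix.with_data(np.log2(matrix.data), scale=LOG2)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-wise mean quantile normalization across the matrix columns.

    Ties within a column all receive the mean of the reference values at the
    rank positions they jointly occupy (mid-rank assignment), so the result
    does not depend on how a sort breaks ties.
    """
    values = matrix.data.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValidationError(
            "quantile normalization needs at least 2 columns "
            f"(got {n_samples}): nothing to normalize against"
        )
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.take_along_axis(values, order, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_samples):
        o = order[:, j]
        s = values[o, j]
        # tie runs in the sorted column share the mean reference value of
        # the positions they occupy
        run = np.concatenate(([0], np.cumsum(s[1:] != s[:-1])))
        run_mean = np.bincount(run, weights=reference) / np.bincount(run)
        out[o, j] = run_mean[run]

    df = matrix.data.copy()
    df.iloc[:, :] = out
    return matrix.with_data(df)
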