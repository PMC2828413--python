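"""Expression preprocessing: quantile normalization and log2 / median centering.

Quantile normalization forces every sample (column) to share one empirical
distribution — the across-sample mean of sorted values.  Ties within a sample
receive the mean of the reference values at their tied rank positions, so the
output multiset per sample is identical for tie-free input and deterministic
otherwise.

Median centering follows the classic two-pass convention: subtract each
feature's median (row pass), then each sample's median (column pass), exactly
one pass each in that order.  After the column pass the row medians are no
longer guaranteed to be zero; only the last pass's zero-median holds.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix, ParseError

__all__ = ["quantile_normalize", "log2_median_center"]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples (columns) to the mean sorted profile.

    Returns a new matrix; feature/sample order is unchanged.
    """
    vals = matrix.values
    if not np.isfinite(vals).all():
        raise ParseError("quantile_normalize requires finite values")
    n, m = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals, dtype=float)
    for j in range(m):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        s = col[order]
        # runs of tied values in sorted order share the mean reference value
        starts = np.flatnonzero(np.r_[True, s[1:] != s[:-1]])
        counts = np.diff(np.r_[starts, n])
        group_mean = np.add.reduceat(ref, starts) / counts
        assigned = np.repeat(group_mean, counts)
        out[order, j] = assigned
    df = matrix.data.copy()
    df.loc[:, :] = out
    return ExpressionMatrix(df)


def log2_median_center(matrix: ExpressionMatrix, already_log2: bool = True) -> ExpressionMatrix:
    """Optionally log2-transform, then median-center rows and then columns.

    Parameters
    ----------
    already_log2
        When False, values must be strictly positive and are log2-transformed
        first; offending cells are listed in the error otherwise.
    """
    vals = matrix.values.astype(float)
    if not already_log2:
        nonpos = vals <= 0
        if nonpos.any():
            rows, cols = np.nonzero(nonpos)
            cells = [
                f"({matrix.feature_ids[r]}, {matrix.sample_ids[c]})"
                for r, c in list(zip(rows, cols))[:10]
            ]
            raise ParseError(
                f"log2 transform requires positive values; offending cell(s): {', '.join(cells)}"
            )
        vals = np.log2(vals)
    vals = vals - np.median(vals, axis=1, keepdims=True)
    vals = vals - np.median(vals, axis=0, keepdims=True)
    df = matrix.data.copy()
    df.loc[:, :] = vals
    return ExpressionMatrix(df)
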