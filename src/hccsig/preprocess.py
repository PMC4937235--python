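"""Log2 transformation and full-quantile normalization.

Quantile normalization forces every sample column to share one empirical
distribution — the across-column mean of order statistics — while
preserving within-column ranks.  Tied values within a column receive the
mean of the tied order-statistic means, which keeps the procedure
deterministic and idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def log2_transform(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Element-wise ``v -> log2(v + pseudocount)``; missing values propagate.

    Raises :class:`ValueError` naming the first offending cell if any
    non-missing ``v + pseudocount`` is not strictly positive.
    """
    shifted = matrix + pseudocount
    bad = (shifted <= 0) & matrix.notna()
    if bad.to_numpy().any():
        row = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[row]][0]
        raise ValueError(
            f"log2_transform: non-positive value {matrix.loc[row, col]!r} + "
            f"pseudocount {pseudocount} at ({row!r}, {col!r})"
        )
    return np.log2(shifted)


def drop_missing_probes(matrix: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop probes with any missing value; returns (filtered, n_dropped)."""
    keep = matrix.notna().all(axis=1)
    return matrix.loc[keep], int((~keep).sum())


def _normalize_column(col: np.ndarray, reference: np.ndarray) -> np.ndarray:
    order = np.argsort(col, kind="stable")
    out = np.empty_like(reference)
    out[order] = reference
    sorted_col = col[order]
    # ties: replace each tied run with the mean of its order-statistic means
    boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
    if len(boundaries) < len(col):
        sums = np.add.reduceat(reference, boundaries)
        lengths = np.diff(np.r_[boundaries, len(col)])
        tied_means = np.repeat(sums / lengths, lengths)
        out[order] = tied_means
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Full-quantile normalization across columns.

    Post-condition: every column's sorted value vector equals the
    across-column mean of order statistics, so any two columns have
    identical empirical distributions (Kolmogorov distance 0).  The map
    is idempotent and rank-preserving within each column.

    Missing values are not supported; filter first (see
    :func:`drop_missing_probes`).
    """
    if matrix.isna().to_numpy().any():
        n = int(matrix.isna().any(axis=1).sum())
        raise ValueError(
            f"quantile_normalize: {n} probes contain missing values; "
            "drop or impute them first (drop_missing_probes)"
        )
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.column_stack(
        [_normalize_column(values[:, j], reference) for j in range(values.shape[1])]
    )
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
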